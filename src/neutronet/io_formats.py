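"""Readers, writers and validated containers for every external artifact.

The canonical matrix dialect is plain TSV with a leading ``id`` header cell
and one feature per row; GCT 1.2 is accepted on read (the two preamble lines
are skipped).  Gene sets use GMT; the sample design and the miRNA target map
are two-column TSV.  Identifiers are opaque, case-sensitive strings — no
translation between annotation systems is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    DuplicateIdentifierError,
    EmptyInputError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger("neutronet")

FEATURE_KINDS = ("gene", "mirna", "exon")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DuplicateIdentifierError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix, features x samples.

    ``data`` is a pandas DataFrame whose index holds feature identifiers and
    whose columns hold sample identifiers.  All values must be finite reals.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature_kind: {self.feature_kind!r}")
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            raise ValidationError("expression values must be finite")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise DesignError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[samples], self.feature_kind)


@dataclass
class SampleDesign:
    """Maps each sample to its phenotype label (e.g. JIA, CF, HC)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sample, label in self.assignments.items():
            if not label:
                raise ValidationError(f"empty phenotype label for sample {sample!r}")

    def phenotype_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise DesignError(f"unknown sample: {sample!r}") from None

    def samples_of(self, label: str) -> list[str]:
        return [s for s, l in self.assignments.items() if l == label]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.assignments.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    @property
    def phenotypes(self) -> list[str]:
        return sorted(set(self.assignments.values()))


@dataclass
class TargetMap:
    """miRNA -> set of predicted target gene identifiers."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if not genes:
                raise ValidationError(f"miRNA {mirna!r} has an empty target set")
            self.targets[mirna] = frozenset(genes)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.targets)

    def unique_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExonMap:
    """exon id -> parent gene id."""

    parent: dict[str, str]

    def __post_init__(self) -> None:
        if not all(self.parent.values()):
            raise ValidationError("every exon must map to a non-empty gene id")

    def gene_of(self, exon: str) -> str:
        return self.parent[exon]

    def exons_of(self) -> dict[str, list[str]]:
        """Gene -> ordered list of its exons."""
        out: dict[str, list[str]] = {}
        for exon, gene in self.parent.items():
            out.setdefault(gene, []).append(exon)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise EmptyInputError(f"empty file: {path}")
    return lines


def read_expression_matrix(path: str | Path, feature_kind: str = "gene") -> ExpressionMatrix:
    """Read a features-x-samples TSV (or GCT 1.2) table of log2 intensities."""
    lines = _read_lines(path)
    gct = lines[0].startswith("#1.2")
    if gct:
        # GCT 1.2: version line, dimension line, then header with Name/Description
        lines = lines[2:]
        if not lines:
            raise EmptyInputError(f"GCT file has no data section: {path}")
    header = lines[0].split("\t")
    drop_desc = gct and len(header) >= 2 and header[1].lower() == "description"
    sample_ids = header[2:] if drop_desc else header[1:]
    _check_unique(sample_ids, "sample")
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if drop_desc:
            fields = [fields[0]] + fields[2:]
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(f"{path}: line {lineno} has {len(fields)} fields, expected {len(sample_ids) + 1}")
        row = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(f"{path}: non-numeric cell at line {lineno}, column {col}: {cell!r}") from None
        ids.append(fields[0])
        rows.append(row)
    if not ids:
        raise EmptyInputError(f"matrix has a header but no data rows: {path}")
    _check_unique(ids, "feature")
    frame = pd.DataFrame(rows, index=ids, columns=sample_ids)
    return ExpressionMatrix(frame, feature_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the canonical TSV dialect (leading ``id`` header cell)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member ids, tab-separated."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: GMT line {lineno} has fewer than 3 fields")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise DuplicateIdentifierError(f"duplicate gene set name: {name!r}")
        members = frozenset(m for m in fields[2:] if m)
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column (miRNA id, gene id) pair list; duplicates collapse."""
    targets: dict[str, set[str]] = {}
    try:
        lines = _read_lines(path)
    except EmptyInputError:
        logger.warning("target map %s is empty", path)
        return TargetMap({})
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}: malformed target-map line {lineno}: {line!r}")
        targets.setdefault(fields[0], set()).add(fields[1])
    return TargetMap({m: frozenset(g) for m, g in targets.items()})


def write_target_map(target_map: TargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in target_map.targets:
            for gene in sorted(target_map.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a two-column (sample id, phenotype) table."""
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}: malformed design line {lineno}: {line!r}")
        if fields[0] in assignments:
            raise DuplicateIdentifierError(f"duplicate sample id: {fields[0]!r}")
        assignments[fields[0]] = fields[1]
    return SampleDesign(assignments)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, label in design.assignments.items():
            fh.write(f"{sample}\t{label}\n")


def read_exon_map(path: str | Path) -> ExonMap:
    """Read a two-column (exon id, gene id) table; each exon maps once."""
    parent: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}: malformed exon-map line {lineno}: {line!r}")
        if fields[0] in parent:
            raise DuplicateIdentifierError(f"exon {fields[0]!r} mapped twice")
        parent[fields[0]] = fields[1]
    return ExonMap(parent)


def write_exon_map(exon_map: ExonMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for exon, gene in exon_map.parent.items():
            fh.write(f"{exon}\t{gene}\n")
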
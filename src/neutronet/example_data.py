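"""Worked-example table: nine miRNAs differentially expressed in JIA neutrophils.

A small fixture of nine miRNA transcripts that distinguish neutrophils of
children with polyarticular juvenile idiopathic arthritis (JIA) from healthy
controls (HC): per-group mean log2 intensities and the two-sample t-test
p-value of each transcript.  The nine rows are the significant head of a
family of ``MIRNA_FAMILY_SIZE`` miRNA tests, which is the ``N`` used by the
rank-based FDR.  Used by the README walk-through and the regression tests of
the signed fold change and FDR conventions.
"""

import pandas as pd

#: total number of miRNAs in the differential-expression test family
MIRNA_FAMILY_SIZE = 847

NINE_MIRNAS = pd.DataFrame(
    [
        ("miR-34a", 3.005, 2.273, 6.47e-06),
        ("miR-936", 1.340, 1.628, 1.44e-04),
        ("miR-127-3p", 3.014, 1.995, 9.03e-05),
        ("miR-409-3p", 3.766, 2.871, 1.28e-04),
        ("miR-933", 3.147, 2.570, 1.93e-04),
        ("miR-379", 2.106, 1.566, 2.27e-04),
        ("miR-494", 4.193, 3.396, 2.60e-04),
        ("miR-551a", 3.438, 2.713, 7.40e-05),
        ("miR-1285", 3.998, 3.412, 9.92e-04),
    ],
    columns=["mirna", "mean_jia_log2", "mean_hc_log2", "p"],
).set_index("mirna")


def nine_mirna_table() -> pd.DataFrame:
    """The fixture with signed fold change and rank-based FDR columns filled."""
    from .diffexpr import custom_fdr, signed_fold_change

    table = NINE_MIRNAS.copy()
    table["signed_fc"] = [
        signed_fold_change(a, b)
        for a, b in zip(table["mean_jia_log2"], table["mean_hc_log2"])
    ]
    fdr, ranks = custom_fdr(table["p"], MIRNA_FAMILY_SIZE)
    table["rank"] = ranks
    table["fdr"] = fdr
    return table
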
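"""Bundled reference tables of published risk-allele statistics.

Two curated panels of the 52 SNPs associated with intraocular-pressure
elevation in open-angle glaucoma ship with the package:

``iop_snps_global.tsv``
    Effect-allele frequency and signed log10 Fisher P per SNP for the
    five 1000 Genomes phase 3 continental groups (AMR, AFR, EAS, SAS,
    EUR) against the pooled global reference (n = 2504 individuals),
    plus the Korean reference cohort (KRGDB, n = 1722).

``iop_snps_east_asian.tsv``
    The same SNPs within East Asia: the five 1000 Genomes East Asian
    populations (CHS, CDX, KHV, CHB, JPT) and the Korean cohort against
    the pooled East Asian reference (n = 504).

Values are as printed in the published summary tables (frequencies
rounded to 2-4 digits, log10 P to 3 digits); allele counts reconstructed
from them therefore carry a rounding caveat.  The companion panel of
135 open-angle-glaucoma-associated SNPs was published only as
supplementary spreadsheets and is not bundled; its loader raises
:class:`~popgrs.errors.DataUnavailableError`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import DataUnavailableError
from .genotypes import AlleleFrequencyTable, FLAG_RECONSTRUCTED

#: diploid cohort sizes behind each column group
COHORT_SIZES: dict[str, int] = {
    "GLOBAL": 2504,
    "AMR": 347, "AFR": 661, "EAS": 504, "SAS": 489, "EUR": 503,
    "KOR": 1722,
    "CHS": 105, "CDX": 93, "KHV": 99, "CHB": 103, "JPT": 104,
}

GLOBAL_POPULATIONS = ("AMR", "AFR", "EAS", "SAS", "EUR", "KOR")
EAST_ASIAN_POPULATIONS = ("CHS", "CDX", "KHV", "CHB", "JPT", "KOR")


def _read(name: str) -> pd.DataFrame:
    with resources.files("popgrs").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_iop_panel(scope: str = "global") -> pd.DataFrame:
    """Load one bundled 52-SNP panel as a flat DataFrame.

    ``scope`` is ``"global"`` (continental groups + KOR vs pooled
    global) or ``"east_asian"`` (East Asian populations + KOR vs pooled
    East Asians).  Columns: variant identity plus ``<POP>_eaf`` and
    ``<POP>_log10p`` per population, and the reference EAF column
    (``global_eaf`` or ``eas_eaf``).
    """
    if scope == "global":
        return _read("iop_snps_global.tsv")
    if scope == "east_asian":
        return _read("iop_snps_east_asian.tsv")
    raise ValueError(f"unknown scope {scope!r}")


def load_oag_panel() -> pd.DataFrame:
    """Per-population frequencies of the 135 OAG-associated SNPs.

    Not bundled: these frequencies were published only as supplementary
    spreadsheet files that are not redistributed with the package, so
    analyses over the 135-SNP set (classification counts, the
    Kruskal-Wallis frequency comparison) cannot be reproduced from
    bundled data.
    """
    raise DataUnavailableError(
        "the 135-SNP OAG panel frequencies are not bundled with popgrs; "
        "only the 52-SNP IOP panel tables are available "
        "(see popgrs.refdata.load_iop_panel)"
    )


def signed_matrix(scope: str = "global") -> pd.DataFrame:
    """rsid x population frame of published signed log10 P values."""
    df = load_iop_panel(scope)
    pops = GLOBAL_POPULATIONS if scope == "global" else EAST_ASIAN_POPULATIONS
    out = df.set_index("rsid")[[f"{p}_log10p" for p in pops]]
    out.columns = list(pops)
    return out


def frequency_table(scope: str = "global") -> AlleleFrequencyTable:
    """Published frequencies as an AlleleFrequencyTable.

    Allele counts are reconstructed as round(eaf * 2n) from the printed
    frequencies and the known cohort sizes; every cell is flagged
    ``reconstructed``.  The pooled reference enters as group ``GLOBAL``
    (or ``EAS_POOL`` for the East Asian panel).
    """
    df = load_iop_panel(scope)
    if scope == "global":
        pops, ref_col, ref_label, ref_n = (
            GLOBAL_POPULATIONS, "global_eaf", "GLOBAL", COHORT_SIZES["GLOBAL"])
    else:
        pops, ref_col, ref_label, ref_n = (
            EAST_ASIAN_POPULATIONS, "eas_eaf", "EAS_POOL", COHORT_SIZES["EAS"])
    rows = []
    for _, r in df.iterrows():
        n = 2 * ref_n
        rows.append((r["rsid"], ref_label, int(round(r[ref_col] * n)), n))
        for p in pops:
            n = 2 * COHORT_SIZES[p]
            rows.append((r["rsid"], p, int(round(r[f"{p}_eaf"] * n)), n))
    return AlleleFrequencyTable.from_counts(rows, flags=FLAG_RECONSTRUCTED)
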
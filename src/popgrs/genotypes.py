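"""Genotype and allele-frequency containers.

Reads multi-sample VCFs (via cyvcf2) against a curated SNP set, holds
effect-allele dosages as a samples x variants matrix, and aggregates
them into per-group effect-allele frequencies (EAF).  Population
membership comes from a 1000-Genomes-style panel file (sample, pop,
super_pop).  Cohorts published only as frequency tables are supported by
reconstructing allele counts from the frequency and the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import SnpAssociation, normalize_chrom
from .errors import ConfigurationError, FormatError, ValidationError

Grouping = Literal["population", "super_population", "pooled"]

#: flag labels attached to AlleleFrequencyTable cells
FLAG_RECONSTRUCTED = "reconstructed"  # counts rebuilt from a rounded frequency
FLAG_NO_CALLS = "no_calls"            # every genotype missing in the group
FLAG_PALINDROMIC = "palindromic"      # A/T or C/G site, strand-ambiguous


@dataclass(frozen=True)
class SamplePanel:
    """sample -> (population, super-population) mapping."""

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        super_of: dict[str, str] = {}
        for sample, (pop, sup) in self.entries.items():
            if pop in super_of and super_of[pop] != sup:
                raise ValidationError(
                    f"population {pop!r} mapped to both {super_of[pop]!r} and {sup!r}"
                )
            super_of[pop] = sup

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SamplePanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "pop", "super_pop"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"panel file must have columns {sorted(required)}, got {list(df.columns)}"
            )
        if df["sample"].duplicated().any():
            dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample ids in panel: {dupes[:5]}")
        return cls({r["sample"]: (r["pop"], r["super_pop"]) for _, r in df.iterrows()})

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("sample\tpop\tsuper_pop\n")
            for sample, (pop, sup) in self.entries.items():
                fh.write(f"{sample}\t{pop}\t{sup}\n")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def group_of(self, sample: str, grouping: Grouping, pooled_label: str = "GLOBAL") -> str:
        if grouping == "pooled":
            return pooled_label
        pop, sup = self.entries[sample]
        return pop if grouping == "population" else sup

    def groups(self, grouping: Grouping, pooled_label: str = "GLOBAL") -> list[str]:
        if grouping == "pooled":
            return [pooled_label]
        idx = 0 if grouping == "population" else 1
        seen: dict[str, None] = {}
        for entry in self.entries.values():
            seen.setdefault(entry[idx], None)
        return list(seen)


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages for samples x variants.

    ``dosage[i, j]`` counts copies of the effect allele of variant ``j``
    carried by sample ``i``; missing genotypes are NaN.
    """

    variants: pd.DataFrame  # columns: rsid, chrom, pos, ref, alt, effect_allele
    samples: list[str]
    dosage: np.ndarray  # float, shape (n_samples, n_variants), NaN = missing

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2} or missing")
        if self.variants["rsid"].duplicated().any():
            raise ValidationError("duplicate variant rsids in genotype matrix")

    @property
    def rsids(self) -> list[str]:
        return self.variants["rsid"].tolist()


@dataclass
class VcfReadReport:
    """What happened to each requested SNP during VCF matching."""

    matched: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)  # multiallelic / allele mismatch


class AlleleFrequencyTable:
    """Per (rsid, group) effect-allele counts and frequencies.

    Backed by a DataFrame with columns rsid, group, effect_count,
    total_count, eaf, flags.  Cells with no callable genotypes carry
    ``total_count`` 0, ``eaf`` NaN and the ``no_calls`` flag.
    """

    COLUMNS = ["rsid", "group", "effect_count", "total_count", "eaf", "flags"]

    def __init__(self, cells: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in cells.columns]
        if missing:
            raise ValidationError(f"frequency table missing columns {missing}")
        cells = cells[self.COLUMNS].reset_index(drop=True)
        bad = cells[(cells["effect_count"] < 0) | (cells["effect_count"] > cells["total_count"])]
        if len(bad):
            raise ValidationError(f"effect_count outside [0, total_count]:\n{bad.head()}")
        defined = cells["total_count"] > 0
        eaf = cells.loc[defined, "eaf"]
        if ((eaf < 0) | (eaf > 1)).any():
            raise ValidationError("eaf outside [0, 1]")
        self.cells = cells

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.cells["group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def rsids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.cells["rsid"]:
            seen.setdefault(r, None)
        return list(seen)

    def get(self, rsid: str, group: str) -> pd.Series:
        hit = self.cells[(self.cells["rsid"] == rsid) & (self.cells["group"] == group)]
        if hit.empty:
            raise KeyError((rsid, group))
        return hit.iloc[0]

    def eaf_matrix(self) -> pd.DataFrame:
        """rsid x group pivot of frequencies (NaN where undefined)."""
        return self.cells.pivot(index="rsid", columns="group", values="eaf")

    def concat(self, other: "AlleleFrequencyTable") -> "AlleleFrequencyTable":
        return AlleleFrequencyTable(pd.concat([self.cells, other.cells], ignore_index=True))

    def to_tsv(self, path: str | Path, precision: int = 6) -> None:
        out = self.cells.copy()
        out["eaf"] = out["eaf"].map(
            lambda v: "" if pd.isna(v) else f"{v:.{precision}f}"
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        df = pd.read_csv(
            path, sep="\t",
            dtype={"rsid": str, "group": str, "flags": str},
        )
        if "flags" not in df.columns:
            df["flags"] = ""
        df["flags"] = df["flags"].fillna("")
        return cls(df)

    @classmethod
    def from_counts(
        cls,
        rows: Iterable[tuple[str, str, int, int]],
        flags: str = "",
    ) -> "AlleleFrequencyTable":
        recs = []
        for rsid, group, k, n in rows:
            recs.append(
                {
                    "rsid": rsid, "group": group,
                    "effect_count": int(k), "total_count": int(n),
                    "eaf": (k / n) if n else float("nan"),
                    "flags": flags if n else _join_flags(flags, FLAG_NO_CALLS),
                }
            )
        return cls(pd.DataFrame(recs, columns=cls.COLUMNS))


def _join_flags(*flags: str) -> str:
    return ";".join(f for f in flags if f)


def _is_palindromic(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def read_vcf_genotypes(
    vcf_path: str | Path, snps: Sequence[SnpAssociation]
) -> tuple[GenotypeMatrix, VcfReadReport]:
    """Extract effect-allele dosages for the given SNPs from a VCF.

    Sites are matched by rsid when the VCF ID field carries one,
    otherwise by (chrom, pos, {ref, alt}).  Only biallelic SNPs are
    used; multiallelic sites and sites whose allele pair disagrees with
    the association record are skipped and reported.  When the effect
    allele is the VCF REF, the dosage is 2 minus the ALT-allele count.
    """
    from cyvcf2 import VCF

    by_rsid = {s.rsid: s for s in snps}
    by_site = {(s.chrom, s.pos): s for s in snps}
    report = VcfReadReport()
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    found: list[SnpAssociation] = []
    for var in vcf:
        snp = by_rsid.get(var.ID) if var.ID else None
        if snp is None:
            snp = by_site.get((normalize_chrom(var.CHROM), var.POS))
        if snp is None:
            continue
        if len(var.ALT) != 1:
            report.skipped.append({"rsid": snp.rsid, "reason": "multiallelic"})
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if {ref, alt} != {snp.ref_allele, snp.alt_allele}:
            report.skipped.append(
                {
                    "rsid": snp.rsid,
                    "reason": f"allele mismatch: VCF {ref}/{alt} vs "
                    f"association {snp.ref_allele}/{snp.alt_allele}",
                }
            )
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        alt_count = var.gt_types.astype(float)
        alt_count[alt_count == 3] = np.nan
        if snp.effect_allele == alt:
            dose = alt_count
        elif snp.effect_allele == ref:
            dose = 2.0 - alt_count
        else:  # ambiguous record whose counting allele is neither: skip
            report.skipped.append(
                {"rsid": snp.rsid, "reason": "effect allele absent from site"}
            )
            continue
        rows.append(dose)
        found.append(snp)
        report.matched.append(snp.rsid)
    matched_ids = set(report.matched) | {s["rsid"] for s in report.skipped}
    report.unmatched = [s.rsid for s in snps if s.rsid not in matched_ids]
    variants = pd.DataFrame(
        {
            "rsid": [s.rsid for s in found],
            "chrom": [s.chrom for s in found],
            "pos": [s.pos for s in found],
            "ref": [s.ref_allele for s in found],
            "alt": [s.alt_allele for s in found],
            "effect_allele": [s.effect_allele for s in found],
        }
    )
    dosage = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(variants, samples, dosage), report


def compute_eaf(
    genotypes: GenotypeMatrix,
    panel: SamplePanel,
    grouping: Grouping = "population",
    pooled_label: str = "GLOBAL",
    whitelist: Iterable[str] | None = None,
) -> AlleleFrequencyTable:
    """Aggregate dosages into per-group effect-allele frequencies.

    Per SNP and group the denominator counts non-missing calls only:
    ``effect_count = sum(dosage)``, ``total_count = 2 x n_called``.
    Samples absent from the panel raise unless whitelisted (whitelisted
    samples are excluded from every group).
    """
    allowed = set(whitelist or ())
    keep_idx, group_labels = [], []
    for i, sample in enumerate(genotypes.samples):
        if sample in panel.entries:
            keep_idx.append(i)
            group_labels.append(panel.group_of(sample, grouping, pooled_label))
        elif sample not in allowed:
            raise ConfigurationError(
                f"sample {sample!r} absent from panel and not whitelisted"
            )
    if not keep_idx:
        raise ConfigurationError("no panel samples present in genotype matrix")
    dose = genotypes.dosage[keep_idx, :]
    labels = np.asarray(group_labels)
    rows = []
    order: dict[str, None] = {}
    for g in group_labels:
        order.setdefault(g, None)
    for group in order:
        sub = dose[labels == group, :]
        called = ~np.isnan(sub)
        n_called = called.sum(axis=0)
        k = np.nansum(sub, axis=0)
        for j, rsid in enumerate(genotypes.rsids):
            total = int(2 * n_called[j])
            flags = ""
            var = genotypes.variants.iloc[j]
            if _is_palindromic(var["ref"], var["alt"]):
                flags = FLAG_PALINDROMIC
            if total == 0:
                rows.append(
                    {
                        "rsid": rsid, "group": group, "effect_count": 0,
                        "total_count": 0, "eaf": float("nan"),
                        "flags": _join_flags(flags, FLAG_NO_CALLS),
                    }
                )
            else:
                rows.append(
                    {
                        "rsid": rsid, "group": group,
                        "effect_count": int(round(k[j])), "total_count": total,
                        "eaf": k[j] / total, "flags": flags,
                    }
                )
    return AlleleFrequencyTable(pd.DataFrame(rows, columns=AlleleFrequencyTable.COLUMNS))


def read_frequency_table(
    path: str | Path,
    group: str,
    cohort_size: int | None = None,
) -> AlleleFrequencyTable:
    """Read a frequency-only cohort table (rsid, eaf[, counts]).

    When allele counts are absent they are reconstructed as
    ``round(eaf * 2 * cohort_size)`` and flagged ``reconstructed`` so
    downstream enrichment outputs can carry a rounding caveat.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    if "rsid" not in df.columns or "eaf" not in df.columns:
        raise FormatError("frequency table must have columns rsid, eaf")
    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        bad = df[(df["eaf"] < 0) | (df["eaf"] > 1)]
        raise ValidationError(f"frequency outside [0, 1]:\n{bad.head()}")
    has_counts = {"effect_count", "total_count"}.issubset(df.columns)
    if not has_counts and cohort_size is None:
        raise ConfigurationError(
            "cohort_size required when the table carries no allele counts"
        )
    rows = []
    for _, r in df.iterrows():
        if has_counts:
            k, n, flags = int(r["effect_count"]), int(r["total_count"]), ""
            eaf = k / n if n else float("nan")
        else:
            n = 2 * int(cohort_size)
            k = int(round(r["eaf"] * n))
            eaf, flags = float(r["eaf"]), FLAG_RECONSTRUCTED
        rows.append(
            {
                "rsid": r["rsid"], "group": group, "effect_count": k,
                "total_count": n, "eaf": eaf, "flags": flags,
            }
        )
    return AlleleFrequencyTable(pd.DataFrame(rows, columns=AlleleFrequencyTable.COLUMNS))
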
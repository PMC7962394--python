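"""Composite genetic risk scores and prevalence correlation.

The score of an individual is the fraction of risk alleles carried over
a SNP set: score = sum(Xi) / (2 I), with Xi the per-SNP count of effect
alleles (0, 1 or 2) and I the number of SNPs used.  A carrier of two
risk alleles at every SNP scores 1, a carrier of none scores 0, and
random uniform assignment of Xi gives an expected score of 0.5.  The
score is deliberately unweighted: per-allele effect sizes estimated in
one ancestry transfer poorly to others, so equal weights are the
default and a log-OR-weighted variant is offered only as an extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)
from .genotypes import AlleleFrequencyTable, GenotypeMatrix, Grouping, SamplePanel


@dataclass(frozen=True)
class IndividualScore:
    sample_id: str
    n_snps_used: int
    score: float


@dataclass(frozen=True)
class PopulationScoreSummary:
    group: str
    n_samples: int
    mean_score: float
    sd_score: float


@dataclass(frozen=True)
class PrevalenceRecord:
    group: str
    oag_prevalence: float
    ntg_proportion: float

    def __post_init__(self) -> None:
        for name in ("oag_prevalence", "ntg_proportion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.group}: {name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    dropped: tuple[str, ...] = ()


def composite_risk_score(
    dosages: Sequence[float], sample_id: str = "", weights: Sequence[float] | None = None
) -> IndividualScore:
    """Score one individual from its per-SNP effect-allele counts.

    Missing dosages (None or NaN) are dropped from both numerator and
    denominator; a sample with no usable SNP is rejected.  ``weights``
    switches to the weighted extension sum(wi Xi) / (2 sum(wi)).
    """
    arr = np.array([np.nan if d is None else float(d) for d in dosages], dtype=float)
    used = ~np.isnan(arr)
    vals = arr[used]
    if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
        bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
        raise ValidationError(f"dosages must be in {{0,1,2}}, got {bad[:5]}")
    n_used = int(used.sum())
    if n_used == 0:
        raise DegenerateInputError(
            f"sample {sample_id or '<anonymous>'}: no usable SNPs (all missing)"
        )
    if weights is None:
        score = float(vals.sum()) / (2.0 * n_used)
    else:
        w = np.asarray(weights, dtype=float)[used]
        if (w < 0).any() or w.sum() == 0:
            raise ValidationError("weights must be non-negative with positive sum")
        score = float((w * vals).sum()) / (2.0 * float(w.sum()))
    return IndividualScore(sample_id=sample_id, n_snps_used=n_used, score=score)


def score_samples(
    genotypes: GenotypeMatrix, snp_set: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample composite scores over a retained SNP set (DataFrame)."""
    rsids = genotypes.rsids
    if snp_set is not None:
        keep = [j for j, r in enumerate(rsids) if r in set(snp_set)]
        if not keep:
            raise DegenerateInputError("retained SNP set shares no SNPs with genotypes")
        dose = genotypes.dosage[:, keep]
    else:
        dose = genotypes.dosage
    rows = []
    for i, sample in enumerate(genotypes.samples):
        sc = composite_risk_score(dose[i, :], sample_id=sample)
        rows.append({"sample": sample, "n_snps_used": sc.n_snps_used, "score": sc.score})
    return pd.DataFrame(rows)


def population_mean_score(
    genotypes: GenotypeMatrix,
    panel: SamplePanel,
    snp_set: Sequence[str] | None = None,
    grouping: Grouping = "super_population",
) -> list[PopulationScoreSummary]:
    """Mean and SD of individual scores per population group.

    With no missing genotypes the group mean equals the group's mean
    EAF over the SNP set (the score is linear in the dosages).
    """
    scores = score_samples(genotypes, snp_set)
    groups: dict[str, list[float]] = {}
    for _, row in scores.iterrows():
        sample = row["sample"]
        if sample not in panel.entries:
            continue
        g = panel.group_of(sample, grouping)
        groups.setdefault(g, []).append(row["score"])
    out = []
    for g, vals in groups.items():
        arr = np.asarray(vals)
        out.append(
            PopulationScoreSummary(
                group=g, n_samples=len(arr),
                mean_score=float(arr.mean()),
                sd_score=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            )
        )
    return out


def phase_concordance_filter(
    freq_a: AlleleFrequencyTable,
    freq_b: AlleleFrequencyTable,
    group_a: str,
    group_b: str,
    candidates: Sequence[str] | None = None,
    cutoff: float = 0.10,
) -> tuple[list[str], pd.DataFrame]:
    """Drop SNPs whose frequency moved by more than ``cutoff`` between
    two releases of the same cohort.

    A SNP is retained iff |eaf_a - eaf_b| <= cutoff (a difference of
    exactly the cutoff is kept; only strictly greater differences are
    excluded).  SNPs absent from either table are excluded with reason
    ``missing``.  Returns (retained rsids, exclusion report frame).
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff must be in [0,1], got {cutoff}")
    a = freq_a.cells[freq_a.cells["group"] == group_a].set_index("rsid")["eaf"]
    b = freq_b.cells[freq_b.cells["group"] == group_b].set_index("rsid")["eaf"]
    if candidates is None:
        candidates = list(dict.fromkeys(list(a.index) + list(b.index)))
    retained, excluded = [], []
    for rsid in candidates:
        if rsid not in a.index or rsid not in b.index:
            excluded.append({"rsid": rsid, "eaf_a": a.get(rsid, float("nan")),
                             "eaf_b": b.get(rsid, float("nan")), "reason": "missing"})
            continue
        ea, eb = float(a[rsid]), float(b[rsid])
        if math.isnan(ea) or math.isnan(eb):
            excluded.append({"rsid": rsid, "eaf_a": ea, "eaf_b": eb, "reason": "missing"})
        elif abs(ea - eb) > cutoff:
            excluded.append(
                {"rsid": rsid, "eaf_a": ea, "eaf_b": eb,
                 "reason": f"frequency difference {abs(ea - eb):.4f} > {cutoff}"}
            )
        else:
            retained.append(rsid)
    report = pd.DataFrame(excluded, columns=["rsid", "eaf_a", "eaf_b", "reason"])
    return retained, report


def high_iop_prevalence(record: PrevalenceRecord) -> float:
    """Prevalence of the high-pressure form: (1 - NTG proportion) x OAG prevalence."""
    return (1.0 - record.ntg_proportion) * record.oag_prevalence


def read_prevalence_table(path: str | Path) -> list[PrevalenceRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"group", "oag_prevalence", "ntg_proportion"}
    if not required.issubset(df.columns):
        raise FormatError(f"prevalence table must have columns {sorted(required)}")
    return [
        PrevalenceRecord(str(r["group"]), float(r["oag_prevalence"]),
                         float(r["ntg_proportion"]))
        for _, r in df.iterrows()
    ]


def correlate_prevalence(
    summaries: Iterable[PopulationScoreSummary],
    prevalences: Iterable[PrevalenceRecord],
    outcome: Literal["oag", "high_iop"] = "oag",
) -> CorrelationResult:
    """Pearson correlation of population mean scores with prevalence.

    Groups present on only one side are dropped and reported.  A
    constant score or prevalence vector has no defined correlation and
    is an error, as is n < 3.
    """
    sc = {s.group: s.mean_score for s in summaries}
    pr = {}
    for p in prevalences:
        pr[p.group] = p.oag_prevalence if outcome == "oag" else high_iop_prevalence(p)
    shared = [g for g in sc if g in pr]
    dropped = tuple(g for g in list(sc) + list(pr) if g not in shared)
    if len(shared) < 3:
        raise DegenerateInputError(
            f"need >= 3 groups with both score and prevalence, got {len(shared)}"
        )
    x = np.array([sc[g] for g in shared])
    y = np.array([pr[g] for g in shared])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateInputError("constant vector: correlation undefined")
    r, _ = pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(shared), dropped=dropped)
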
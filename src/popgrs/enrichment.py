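"""Signed log-scale Fisher enrichment of effect alleles per population.

For each SNP and population the 2x2 table

    [[k_pop, n_pop - k_pop],
     [k_ref, n_ref - k_ref]]

(effect vs other allele counts in the population and a reference pool)
is tested with a two-sided Fisher exact test.  The statistic reported is
the *signed* log10 P value: ``-log10(P)`` (positive) when the population
frequency exceeds the reference — the allele is enriched — and
``+log10(P)`` (negative) when it is below — depleted.  At the
conventional P < 0.05 cut this gives the classification threshold
|signed log10 P| > 1.301.

The hypergeometric summation is carried out entirely in log space
(log-gamma terms combined with logsumexp), because cohorts of a few
thousand chromosomes routinely produce P values far below the smallest
positive double (|log10 P| beyond 300): the signed statistic stays exact
there even when the linear-scale P underflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import gammaln, logsumexp
from scipy.stats import kruskal

from .errors import ConfigurationError, ValidationError
from .genotypes import AlleleFrequencyTable

#: |signed log10 P| above this is significant (P < 0.05)
DEFAULT_THRESHOLD = 1.301

#: smallest positive double; P values below it are floored and flagged
_TINY = np.nextafter(0.0, 1.0)

#: relative tolerance for "as extreme" probability comparison, matching the
#: convention of R's fisher.test
_REL_TOL = 1e-7

Klass = Literal["enriched", "depleted", "similar"]
Alternative = Literal["two-sided", "enrichment", "depletion"]


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    signed_log10p: float
    saturated: bool  # True when p underflowed the linear scale


@dataclass(frozen=True)
class EnrichmentCell:
    rsid: str
    group: str
    eaf_pop: float
    eaf_ref: float
    p_two_sided: float
    signed_log10p: float
    klass: Klass
    saturated: bool = False
    flags: str = ""


def _check_count(name: str, value: int) -> int:
    if isinstance(value, float) and not float(value).is_integer():
        raise ValidationError(f"{name} must be an integer, got {value}")
    value = int(value)
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


def _log_hypergeom_pmf(x: np.ndarray, n1: int, n2: int, K: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom(N=n1+n2, K, n1), via log-gamma."""
    N = n1 + n2

    def lchoose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return lchoose(n1, x) + lchoose(n2, K - x) - lchoose(N, K)


def fisher_signed_log10p(
    k_pop: int, n_pop: int, k_ref: int, n_ref: int,
    alternative: Alternative = "two-sided",
) -> FisherResult:
    """Two-sided Fisher exact test with a frequency-signed log10 P.

    Returns the two-sided P (floored at the smallest positive double
    with ``saturated=True`` when it underflows) and the signed log10 P:
    positive for enrichment (eaf_pop > eaf_ref), negative for depletion,
    zero when the frequencies are equal.  One-sided modes sum only the
    tail at or beyond the observed count in the named direction.
    """
    k_pop = _check_count("k_pop", k_pop)
    n_pop = _check_count("n_pop", n_pop)
    k_ref = _check_count("k_ref", k_ref)
    n_ref = _check_count("n_ref", n_ref)
    if n_pop < 1 or n_ref < 1:
        raise ValidationError("allele totals must be >= 1")
    if k_pop > n_pop or k_ref > n_ref:
        raise ValidationError("effect count exceeds total count")

    K = k_pop + k_ref
    lo, hi = max(0, K - n_ref), min(K, n_pop)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, n_pop, n_ref, K)
    obs = logpmf[k_pop - lo]
    if alternative == "two-sided":
        mask = logpmf <= obs + math.log1p(_REL_TOL)
    elif alternative == "enrichment":
        mask = support >= k_pop
    elif alternative == "depletion":
        mask = support <= k_pop
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    logp = 0.0 if mask.all() else min(0.0, float(logsumexp(logpmf[mask])))
    log10p = logp / math.log(10)

    p = math.exp(logp)
    saturated = p < _TINY or (p == 0.0 and logp > -math.inf)
    if p < _TINY:
        p = _TINY

    eaf_pop, eaf_ref = k_pop / n_pop, k_ref / n_ref
    if eaf_pop > eaf_ref:
        signed = -log10p
    elif eaf_pop < eaf_ref:
        signed = log10p
    else:
        signed = 0.0
    return FisherResult(p_two_sided=p, signed_log10p=signed, saturated=saturated)


def classify(signed_log10p: float, threshold: float = DEFAULT_THRESHOLD) -> Klass:
    """Strictly-greater threshold rule on the signed statistic."""
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if signed_log10p > threshold:
        return "enriched"
    if signed_log10p < -threshold:
        return "depleted"
    return "similar"


@dataclass
class EnrichmentMatrix:
    """SNPs x populations grid of signed log10 P values and classes."""

    values: pd.DataFrame   # index rsid, columns group, float (NaN = missing)
    classes: pd.DataFrame  # same shape, str or NaN
    cells: list[EnrichmentCell]
    reference: str
    threshold: float = DEFAULT_THRESHOLD
    missing: list[dict] = field(default_factory=list)

    def class_counts(self) -> dict[str, dict[str, int]]:
        """Per-group counts of enriched / depleted / similar cells."""
        out: dict[str, dict[str, int]] = {}
        for group in self.classes.columns:
            col = self.classes[group].dropna()
            out[group] = {
                "enriched": int((col == "enriched").sum()),
                "depleted": int((col == "depleted").sum()),
                "similar": int((col == "similar").sum()),
            }
        return out

    def to_cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.cells])


def build_matrix(
    freqs: AlleleFrequencyTable,
    snps: Sequence[str],
    groups: Sequence[str],
    reference: str,
    threshold: float = DEFAULT_THRESHOLD,
    alternative: Alternative = "two-sided",
    exclude_focal: bool = False,
) -> EnrichmentMatrix:
    """Assemble the signed log10 P matrix of every (SNP, group) cell.

    ``reference`` names the pooled reference group in ``freqs``; it is
    not itself a matrix column.  With ``exclude_focal`` the focal
    group's own alleles are subtracted from the reference pool before
    testing (statistically independent comparison); the default keeps
    the pool as-is, i.e. the focal population is part of the global
    reference it is compared against.  Undefined frequency cells
    propagate as missing with a reason, not an error.
    """
    if reference not in freqs.groups:
        raise ConfigurationError(f"reference group {reference!r} absent from table")
    test_groups = [g for g in groups if g != reference]
    values = pd.DataFrame(index=list(snps), columns=test_groups, dtype=float)
    classes = pd.DataFrame(index=list(snps), columns=test_groups, dtype=object)
    cells: list[EnrichmentCell] = []
    missing: list[dict] = []
    for rsid in snps:
        try:
            ref_cell = freqs.get(rsid, reference)
        except KeyError:
            for g in test_groups:
                missing.append({"rsid": rsid, "group": g, "reason": "reference cell absent"})
            continue
        for group in test_groups:
            try:
                cell = freqs.get(rsid, group)
            except KeyError:
                missing.append({"rsid": rsid, "group": group, "reason": "cell absent"})
                continue
            if cell["total_count"] == 0 or ref_cell["total_count"] == 0:
                missing.append({"rsid": rsid, "group": group, "reason": "no calls"})
                continue
            k_ref, n_ref = int(ref_cell["effect_count"]), int(ref_cell["total_count"])
            if exclude_focal:
                k_ref -= int(cell["effect_count"])
                n_ref -= int(cell["total_count"])
                if n_ref < 1 or k_ref < 0:
                    raise ConfigurationError(
                        f"{rsid}/{group}: focal counts exceed reference pool; "
                        "exclude_focal requires the reference to contain the group"
                    )
            res = fisher_signed_log10p(
                int(cell["effect_count"]), int(cell["total_count"]),
                k_ref, n_ref, alternative=alternative,
            )
            klass = classify(res.signed_log10p, threshold)
            values.loc[rsid, group] = res.signed_log10p
            classes.loc[rsid, group] = klass
            cells.append(
                EnrichmentCell(
                    rsid=rsid, group=group,
                    eaf_pop=float(cell["eaf"]), eaf_ref=k_ref / n_ref,
                    p_two_sided=res.p_two_sided,
                    signed_log10p=res.signed_log10p,
                    klass=klass, saturated=res.saturated,
                    flags=str(cell["flags"] or ""),
                )
            )
    return EnrichmentMatrix(
        values=values, classes=classes, cells=cells,
        reference=reference, threshold=threshold, missing=missing,
    )


@dataclass
class ClusterTree:
    """Agglomerative clustering of matrix columns (populations)."""

    labels: list[str]          # leaf labels, lexicographic input order
    linkage_matrix: np.ndarray
    newick: str
    n_imputed: int = 0

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition the leaves into k clusters at the appropriate height."""
        assignment = fcluster(self.linkage_matrix, k, criterion="maxclust")
        clusters: dict[int, set[str]] = {}
        for label, c in zip(self.labels, assignment):
            clusters.setdefault(c, set()).add(label)
        return sorted((frozenset(v) for v in clusters.values()), key=sorted)


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        parts = []
        for child in (int(a), int(b)):
            blen = h - heights[child]
            parts.append(f"{render(child)}:{blen:.6f}")
        return f"({','.join(parts)})"

    for idx, (a, b, h, _) in enumerate(Z):
        heights[n + idx] = h
    return render(n + len(Z) - 1) + ";"


def cluster_populations(
    matrix: EnrichmentMatrix,
    metric: Literal["correlation", "euclidean"] = "correlation",
    method: Literal["average", "complete", "ward", "single"] = "average",
) -> ClusterTree:
    """Cluster populations by their enrichment profiles.

    Missing cells are imputed as 0 (no evidence of deviation from the
    reference) and counted.  Columns are ordered lexicographically
    before linkage so ties resolve deterministically.  The default
    metric is correlation distance (1 - Pearson r between the signed
    log10 P profiles): the magnitude of the statistic grows with cohort
    size, so pattern similarity rather than raw distance is what groups
    populations of unequal size; Euclidean distance is available for
    magnitude-aware clustering.
    """
    if matrix.values.shape[1] < 2:
        raise ConfigurationError("clustering needs at least 2 population columns")
    cols = sorted(matrix.values.columns)
    data = matrix.values[cols].to_numpy(dtype=float).T  # populations x SNPs
    n_imputed = int(np.isnan(data).sum())
    data = np.nan_to_num(data, nan=0.0)
    dist = pdist(data, metric=metric)
    Z = linkage(dist, method=method)
    return ClusterTree(
        labels=cols,
        linkage_matrix=Z,
        newick=_linkage_to_newick(Z, cols),
        n_imputed=n_imputed,
    )


def kruskal_wallis_eaf(
    freqs: AlleleFrequencyTable, groups: Sequence[str]
) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test of the per-SNP EAF distributions.

    Each group contributes its vector of effect-allele frequencies over
    the SNP set.  The all-ties degenerate case (identical values
    everywhere) is reported as H = 0, P = 1.
    """
    if len(groups) < 2:
        raise ConfigurationError("Kruskal-Wallis needs at least 2 groups")
    samples = []
    for g in groups:
        vals = freqs.cells.loc[freqs.cells["group"] == g, "eaf"].dropna().to_numpy()
        if vals.size == 0:
            raise ConfigurationError(f"group {g!r} contributes no frequencies")
        samples.append(vals)
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = kruskal(*samples)
    return float(h), float(p)
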
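"""Structured multi-population genotype simulation with known truth.

The generator emulates the shape of a 1000-Genomes-style resource:
populations nested in super-groups, a global allele frequency per SNP,
population-specific drift, and diploid Hardy-Weinberg genotypes.  Drift
follows the Balding-Nichols model: the frequency of a population with
drift coefficient F is Beta(p(1-F)/F, (1-p)(1-F)/F) around the global
frequency p, which has mean p and variance p(1-p)F — closed-form moments
that make parameter-recovery tests exact.  Frequencies fixed at 0 or 1
pass through unchanged.

Everything is written in the exact formats the pipeline consumes (VCF
4.2, panel/association/prevalence TSV) so every stage is testable
without any external download, and every draw is reproducible from the
spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotypes import GenotypeMatrix, SamplePanel


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    super_group: str
    n_samples: int
    fst: float  # Balding-Nichols drift coefficient F

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"{self.label}: n_samples must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValidationError(f"{self.label}: F must be in (0,1), got {self.fst}")


@dataclass
class SyntheticPanelSpec:
    """Parameters of one synthetic genotype panel.

    ``shifts`` lists (snp_index, population_label, delta): the
    population's target frequency at that SNP becomes global + delta
    before drift is applied.  Shifted frequencies must stay in [0, 1].
    """

    n_snps: int
    populations: list[PopulationSpec]
    seed: int
    freq_range: tuple[float, float] = (0.05, 0.95)
    shifts: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(f"invalid frequency range {self.freq_range}")
        labels = {p.label for p in self.populations}
        for idx, label, _ in self.shifts:
            if not (0 <= idx < self.n_snps):
                raise ValidationError(f"shift SNP index {idx} out of range")
            if label not in labels:
                raise ValidationError(f"shift population {label!r} unknown")


def simulate_population_frequencies(
    p_global: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-SNP population frequencies under Balding-Nichols drift."""
    p = np.asarray(p_global, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("global frequencies must lie in [0, 1]")
    if not (0.0 < fst < 1.0):
        raise ValidationError(f"F must be in (0,1), got {fst}")
    scale = (1.0 - fst) / fst
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]  # fixed alleles pass through
    if interior.any():
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def simulate_genotypes(
    pop_freqs: dict[str, np.ndarray],
    n_samples: dict[str, int],
    seed: int,
    super_group_of: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, SamplePanel]:
    """Draw HWE genotypes: dosage ~ Binomial(2, p_pop) per sample and SNP.

    ``pop_freqs`` maps population label to its per-SNP frequency vector;
    all vectors must share one length.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    lengths = {len(v) for v in pop_freqs.values()}
    if len(lengths) != 1:
        raise ValidationError("all populations must cover the same SNPs")
    (n_snps,) = lengths
    blocks, sample_ids, entries = [], [], {}
    for label, p in pop_freqs.items():
        p = np.asarray(p, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError(f"{label}: frequencies must lie in [0, 1]")
        n = int(n_samples[label])
        if n < 1:
            raise ValidationError(f"{label}: n_samples must be >= 1")
        blocks.append(rng.binomial(2, p, size=(n, n_snps)).astype(float))
        for i in range(n):
            sid = f"{label}_{i:04d}"
            sample_ids.append(sid)
            sup = (super_group_of or {}).get(label, label)
            entries[sid] = (label, sup)
    matrix = GenotypeMatrix(
        variants=_variant_frame(n_snps), samples=sample_ids, dosage=np.vstack(blocks)
    )
    return matrix, SamplePanel(entries)


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    panel: SamplePanel
    p_global: np.ndarray
    p_pop: dict[str, np.ndarray]  # post-shift, post-drift frequencies
    truth: dict


def _variant_frame(n_snps: int) -> pd.DataFrame:
    # rsIDs synthesized from 900000 up to avoid collision with real ids
    return pd.DataFrame(
        {
            "rsid": [f"rs{900000 + i}" for i in range(n_snps)],
            "chrom": ["1"] * n_snps,
            "pos": [1000 * (i + 1) for i in range(n_snps)],
            "ref": ["A"] * n_snps,
            "alt": ["G"] * n_snps,
            "effect_allele": ["G"] * n_snps,
        }
    )


def generate_panel(spec: SyntheticPanelSpec) -> SyntheticDataset:
    """Simulate the full panel: frequencies, drift, HWE genotypes.

    Per sample and SNP the effect-allele dosage is Binomial(2, p_pop)
    (Hardy-Weinberg equilibrium).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.freq_range
    p_global = rng.uniform(lo, hi, size=spec.n_snps)

    shift_of: dict[str, np.ndarray] = {
        p.label: np.zeros(spec.n_snps) for p in spec.populations
    }
    for idx, label, delta in spec.shifts:
        shift_of[label][idx] += delta

    p_pop: dict[str, np.ndarray] = {}
    dosage_blocks, sample_ids, panel_entries = [], [], {}
    for pop in spec.populations:
        target = p_global + shift_of[pop.label]
        if ((target < 0) | (target > 1)).any():
            raise ValidationError(
                f"{pop.label}: shifted frequency outside [0, 1]"
            )
        p = simulate_population_frequencies(target, pop.fst, rng)
        p_pop[pop.label] = p
        dosage_blocks.append(
            rng.binomial(2, p, size=(pop.n_samples, spec.n_snps)).astype(float)
        )
        for i in range(pop.n_samples):
            sid = f"{pop.label}_{i:04d}"
            sample_ids.append(sid)
            panel_entries[sid] = (pop.label, pop.super_group)

    genotypes = GenotypeMatrix(
        variants=_variant_frame(spec.n_snps),
        samples=sample_ids,
        dosage=np.vstack(dosage_blocks),
    )
    truth = {
        "seed": spec.seed,
        "p_global": p_global.tolist(),
        "p_pop": {k: v.tolist() for k, v in p_pop.items()},
        "shifts": [[i, l, d] for i, l, d in spec.shifts],
    }
    return SyntheticDataset(
        genotypes=genotypes, panel=SamplePanel(panel_entries),
        p_global=p_global, p_pop=p_pop, truth=truth,
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Serialize dosages as an unphased diploid VCF 4.2 (GT only)."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgrs-simulate\n")
        for chrom in dict.fromkeys(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        for j, var in genotypes.variants.iterrows():
            # dosage counts the effect allele; GT encodes the ALT allele
            flip = var["effect_allele"] == var["ref"]
            calls = []
            for d in genotypes.dosage[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    alt_count = 2.0 - d if flip else d
                    calls.append(gt_of[alt_count])
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['rsid']}\t{var['ref']}\t"
                f"{var['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_association_tsv(variants: pd.DataFrame, path: str | Path, trait: str = "OAG") -> None:
    """Association table in the catalog dialect (risk allele as rsID-X)."""
    with Path(path).open("w") as fh:
        fh.write("rsid\tchrom\tpos\trisk_allele\tref\talt\todds_ratio\n")
        for _, v in variants.iterrows():
            fh.write(
                f"{v['rsid']}\t{v['chrom']}\t{v['pos']}\t"
                f"{v['rsid']}-{v['effect_allele']}\t{v['ref']}\t{v['alt']}\t1.2\n"
            )


DEFAULT_SUPER_GROUPS = ("WEST", "EAST")


def scenario_two_clusters(
    outdir: str | Path,
    n_snps: int = 60,
    n_shifted: int | None = None,
    shift: float = 0.25,
    n_samples: int = 200,
    fst: float = 5e-4,
    seed: int = 7,
) -> dict:
    """Write a complete fixture with a recoverable two-block structure.

    Six populations in two super-groups receive opposite frequency
    shifts (+shift / -shift) on the first ``n_shifted`` SNPs; the
    remaining SNPs are null.  Because the two blocks are equal-sized and
    the shifts symmetric, the pooled frequency stays near the global
    value and the designed cells are truly enriched (or depleted)
    against the pooled reference.  The within-super-group drift is kept
    small so the designed shifts dominate the structure.  Ground truth
    (true frequencies, per-cell expected class, expected top-level
    partition) is recorded in truth.json.
    """
    if n_shifted is None:
        n_shifted = max(1, n_snps // 3)
    if n_shifted > n_snps:
        raise ValidationError(f"n_shifted {n_shifted} exceeds n_snps {n_snps}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    west, east = DEFAULT_SUPER_GROUPS
    pops = [
        PopulationSpec("POP1", west, n_samples, fst),
        PopulationSpec("POP2", west, n_samples, fst),
        PopulationSpec("POP3", west, n_samples, fst),
        PopulationSpec("POP4", east, n_samples, fst),
        PopulationSpec("POP5", east, n_samples, fst),
        PopulationSpec("POP6", east, n_samples, fst),
    ]
    rng = np.random.default_rng(seed)
    # draw shifted-SNP globals away from the boundary so +-shift stays legal
    shifts: list[tuple[int, str, float]] = []
    for i in range(n_shifted):
        for p in pops:
            delta = shift if p.super_group == west else -shift
            shifts.append((i, p.label, delta))
    spec = SyntheticPanelSpec(
        n_snps=n_snps,
        populations=pops,
        seed=int(rng.integers(0, 2**31 - 1)),
        freq_range=(shift + 0.05, 1.0 - shift - 0.05),
        shifts=shifts,
    )
    data = generate_panel(spec)

    write_vcf(data.genotypes, outdir / "genotypes.vcf")
    data.panel.to_tsv(outdir / "panel.tsv")
    write_association_tsv(data.genotypes.variants, outdir / "associations.tsv")
    with (outdir / "prevalence.tsv").open("w") as fh:
        fh.write("group\toag_prevalence\tntg_proportion\n")
        for sup, prev, ntg in ((west, 0.035, 0.35), (east, 0.025, 0.75)):
            fh.write(f"{sup}\t{prev}\t{ntg}\n")

    expected_class = {}
    for p in pops:
        for i in range(n_snps):
            if i < n_shifted:
                expected_class[f"rs{900000 + i}:{p.label}"] = (
                    "enriched" if p.super_group == west else "depleted"
                )
            else:
                expected_class[f"rs{900000 + i}:{p.label}"] = "similar"
    truth = dict(
        data.truth,
        expected_class=expected_class,
        expected_partition=[
            sorted(p.label for p in pops if p.super_group == west),
            sorted(p.label for p in pops if p.super_group == east),
        ],
        n_shifted=n_shifted,
        shift=shift,
    )
    with (outdir / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
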
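"""Curation of GWAS-catalog-style association tables.

A GWAS catalog export reports, per associated variant, a "strongest
SNP-risk allele" in the ``rsID-X`` notation together with an odds ratio
or a beta coefficient.  The reported allele is not always the allele that
*increases* risk: when the odds ratio is below one (or the beta is
negative) the effect runs through the other allele of the biallelic
pair.  This module parses such tables, resolves the effect (risk) allele
by the sign of the direction evidence, and deduplicates the result into
a working SNP set keyed on (rsid, trait).

Records whose direction cannot be determined (risk allele printed as
``?``, odds ratio exactly 1, beta exactly 0, or no direction field at
all) are kept but flagged ``ambiguous``: dropping every variant with an
undefined risk allele would bias the downstream population comparison,
so the reported allele is used as the counting allele and the flag is
propagated to all outputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import FormatError, HarmonizationError, ValidationError

Orientation = Literal["as_reported", "flipped", "ambiguous"]
Trait = Literal["OAG", "IOP"]
DirectionEvidence = Literal["beta_sign", "odds_ratio", "text_description", "none"]

_BASES = frozenset("ACGT")

#: Header aliases accepted for each logical column.  The first group is the
#: GWAS-catalog export dialect, the second a minimal TSV dialect.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "rsid": ("SNPS", "rsid", "snp", "snp_id"),
    "chrom": ("CHR_ID", "chrom", "chr", "chromosome"),
    "pos": ("CHR_POS", "pos", "position"),
    "risk_allele": ("STRONGEST SNP-RISK ALLELE", "risk_allele", "strongest_snp_risk_allele"),
    "ref": ("ref", "ref_allele", "REF"),
    "alt": ("alt", "alt_allele", "ALT"),
    "odds_ratio": ("OR or BETA", "odds_ratio", "or"),
    "beta": ("beta",),
    "source_id": ("STUDY ACCESSION", "source_id", "study"),
}

REQUIRED_COLUMNS = ("rsid", "chrom", "pos", "risk_allele", "ref", "alt")


@dataclass(frozen=True)
class SnpAssociation:
    """One curated association record.

    ``effect_allele`` is the allele counted by every downstream stage; it
    is a member of ``{ref_allele, alt_allele}`` unless ``orientation`` is
    ``ambiguous``.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect_allele: str
    orientation: Orientation = "as_reported"
    trait: Trait = "OAG"
    direction_evidence: DirectionEvidence = "none"
    source_id: str = ""
    odds_ratio: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        # Membership of the effect allele in {ref, alt} is enforced at
        # harmonization time (HarmonizationError with quarantine), not at
        # construction, so freshly parsed rows can carry a bad reported
        # allele long enough to be reported.
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1, got {self.pos}")

    @property
    def other_allele(self) -> str:
        """The non-effect member of the biallelic pair."""
        return self.alt_allele if self.effect_allele == self.ref_allele else self.ref_allele


@dataclass
class CurationReport:
    """Bookkeeping for one parse/harmonize/deduplicate pass."""

    n_parsed: int = 0
    n_rejected_no_rsid: int = 0
    n_quarantined: int = 0
    quarantined: list[dict] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0
    n_removed: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def normalize_chrom(label: str, style: Literal["bare", "chr"] = "bare") -> str:
    """Normalize a chromosome label to ``"7"`` (bare) or ``"chr7"``."""
    bare = label[3:] if label.lower().startswith("chr") else label
    return bare if style == "bare" else f"chr{bare}"


def _resolve_columns(header: Sequence[str], column_map: dict | None) -> dict[str, str]:
    aliases = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        for key, name in column_map.items():
            aliases[key] = (name,) + tuple(aliases.get(key, ()))
    lower = {h.lower(): h for h in header}
    resolved = {}
    for key, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[key] = lower[name.lower()]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return resolved


def _parse_risk_allele(notation: str, rsid: str) -> str | None:
    """Extract the allele letter from ``rsID-X`` notation; None when ``?``."""
    token = notation.strip()
    if "-" in token:
        token = token.rsplit("-", 1)[1]
    token = token.strip().upper()
    if token in ("?", ""):
        return None
    return token


def parse_association_table(
    path: str | Path,
    trait: Trait,
    column_map: dict | None = None,
    chrom_style: Literal["bare", "chr"] = "bare",
    report: CurationReport | None = None,
) -> list[SnpAssociation]:
    """Parse a GWAS-catalog-style TSV into raw association records.

    Rows without an rsID are rejected (counted in the report); an
    unparsable position raises :class:`FormatError` with the line number.
    The effect allele is taken from the ``rsID-X`` suffix as reported;
    direction resolution is a separate step (:func:`resolve_effect_allele`).
    """
    path = Path(path)
    report = report if report is not None else CurationReport()
    records: list[SnpAssociation] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        cols = _resolve_columns(header, column_map)
        idx = {k: header.index(v) for k, v in cols.items()}
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            rsid = row[idx["rsid"]].strip()
            if not rsid:
                report.n_rejected_no_rsid += 1
                continue
            try:
                pos = int(row[idx["pos"]].strip())
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparsable position {row[idx['pos']]!r}"
                ) from None
            ref = row[idx["ref"]].strip().upper()
            alt = row[idx["alt"]].strip().upper()
            reported = _parse_risk_allele(row[idx["risk_allele"]], rsid)
            odds_ratio = beta = None
            evidence: DirectionEvidence = "none"
            if "odds_ratio" in idx and row[idx["odds_ratio"]].strip():
                odds_ratio = float(row[idx["odds_ratio"]])
                evidence = "odds_ratio"
            if "beta" in idx and row[idx["beta"]].strip():
                beta = float(row[idx["beta"]])
                evidence = "beta_sign"
            if reported is None:
                orientation: Orientation = "ambiguous"
                effect = alt  # counting convention for undefined risk alleles
            else:
                orientation = "as_reported"
                effect = reported
            records.append(
                SnpAssociation(
                    rsid=rsid,
                    chrom=normalize_chrom(row[idx["chrom"]].strip(), chrom_style),
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    effect_allele=effect,
                    orientation=orientation,
                    trait=trait,
                    direction_evidence=evidence,
                    source_id=row[idx["source_id"]].strip() if "source_id" in idx else "",
                    odds_ratio=odds_ratio,
                    beta=beta,
                )
            )
            report.n_parsed += 1
    return records


def resolve_effect_allele(record: SnpAssociation) -> SnpAssociation:
    """Orient the effect allele by the sign of the direction evidence.

    Odds ratio below 1 or beta below 0 means the reported allele is
    protective: the effect allele is switched to the other member of the
    pair and the record is marked ``flipped``.  Evidence exactly at the
    null (OR = 1, beta = 0) or absent leaves the direction undefined and
    the record is flagged ``ambiguous`` but kept.

    Raises :class:`HarmonizationError` when the reported allele matches
    neither ref nor alt (caller should quarantine the record).
    """
    if record.orientation == "ambiguous":
        return record
    if record.effect_allele not in (record.ref_allele, record.alt_allele):
        raise HarmonizationError(
            f"{record.rsid}: reported allele {record.effect_allele!r} matches "
            f"neither ref {record.ref_allele!r} nor alt {record.alt_allele!r}"
        )
    direction = 0.0
    if record.beta is not None:
        direction = record.beta
    elif record.odds_ratio is not None:
        direction = record.odds_ratio - 1.0
    else:
        return replace(record, orientation="ambiguous")
    if direction > 0:
        return record
    if direction < 0:
        return replace(
            record, effect_allele=record.other_allele, orientation="flipped"
        )
    return replace(record, orientation="ambiguous")


def harmonize(
    records: Iterable[SnpAssociation], report: CurationReport | None = None
) -> list[SnpAssociation]:
    """Resolve effect alleles for all records, quarantining failures."""
    report = report if report is not None else CurationReport()
    out = []
    for rec in records:
        try:
            out.append(resolve_effect_allele(rec))
        except HarmonizationError as exc:
            report.n_quarantined += 1
            report.quarantined.append({"rsid": rec.rsid, "reason": str(exc)})
    return out


def deduplicate(
    records: Sequence[SnpAssociation], report: CurationReport | None = None
) -> tuple[list[SnpAssociation], CurationReport]:
    """Collapse records to one per (rsid, trait).

    The first occurrence keeps its place in the output order; when a later
    duplicate has resolved orientation and the current survivor is
    ambiguous, the resolved copy replaces it in the same slot.
    """
    report = report if report is not None else CurationReport()
    survivors: dict[tuple[str, str], int] = {}
    out: list[SnpAssociation] = []
    for rec in records:
        key = (rec.rsid, rec.trait)
        if key not in survivors:
            survivors[key] = len(out)
            out.append(rec)
        else:
            slot = survivors[key]
            if out[slot].orientation == "ambiguous" and rec.orientation != "ambiguous":
                out[slot] = rec
    report.n_in = len(records)
    report.n_out = len(out)
    report.n_removed = len(records) - len(out)
    return out, report


def write_association_tsv(records: Iterable[SnpAssociation], path: str | Path) -> None:
    """Write the harmonized association set in the package's 8-column dialect."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["rsid", "chrom", "pos", "ref", "alt", "effect_allele", "orientation", "trait"]
        )
        for r in records:
            writer.writerow(
                [r.rsid, r.chrom, r.pos, r.ref_allele, r.alt_allele,
                 r.effect_allele, r.orientation, r.trait]
            )
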
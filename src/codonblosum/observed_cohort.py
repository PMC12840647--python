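"""Cohort mutation tables: parsing, validation and observed summaries.

Input is a "MAF-lite" TSV — the minimal subset of a Mutation Annotation
Format table needed here: case_id, gene, protein_change (HGVSp-style),
variant_class. A thin adapter accepts standard GDC MAF column names.

A cohort is counted per event: a recurrent variant contributes once per
case it appears in (cohort frequency carries the selection signal), while
identical calls repeated for the same case — e.g. from paired biospecimens
— are collapsed by default. Nonsense calls are parsed and counted but never
scored: BLOSUM is undefined for STOP, matching the neutral event set which
excludes nonsense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .blosum_scoring import BLOSUM62, RADICAL_THRESHOLD, SubstitutionMatrix
from .codon_core import (
    DomainMap,
    GeneModel,
    HgvspParseError,
    ProteinVariant,
    VariantValidationError,
    assign_domain,
    parse_hgvsp,
    validate_variant,
)

logger = logging.getLogger(__name__)

MAF_LITE_COLUMNS = ("case_id", "gene", "protein_change", "variant_class")

#: GDC MAF column names mapped onto MAF-lite.
GDC_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "case_id",
    "Hugo_Symbol": "gene",
    "HGVSp_Short": "protein_change",
    "Variant_Classification": "variant_class",
}

_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
}


class CohortError(ValueError):
    """Raised for malformed cohort tables or empty cohorts."""


def read_maf_lite(
    table_path: str | Path,
    gene_id: str,
    per_biospecimen: bool = False,
) -> list[ProteinVariant]:
    """Read a MAF-lite TSV and return parsed variants for one gene.

    Rows are filtered to ``gene_id`` and variant classes missense/nonsense.
    Unparseable protein-change labels are skipped with a logged warning and
    a final skip count. Duplicate (case_id, protein_change) rows collapse to
    one event per case unless ``per_biospecimen`` keeps them.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    missing = [c for c in MAF_LITE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{table_path}: missing MAF-lite columns {missing}")

    df = df[df["gene"] == gene_id]
    df = df[df["variant_class"].str.lower().map(_CLASS_ALIASES).notna()]

    variants: list[ProteinVariant] = []
    seen: set[tuple[str, str]] = set()
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            v = parse_hgvsp(row.protein_change, case_id=row.case_id, gene_id=gene_id)
        except HgvspParseError as exc:
            n_skipped += 1
            logger.warning("skipping row for case %s: %s", row.case_id, exc)
            continue
        key = (v.case_id, f"{v.wt_aa}{v.position}{v.mut_aa}")
        if not per_biospecimen:
            if key in seen:
                continue
            seen.add(key)
        variants.append(v)
    if n_skipped:
        logger.warning(
            "%s: skipped %d unparseable protein_change rows for %s",
            table_path,
            n_skipped,
            gene_id,
        )
    return variants


def read_gdc_maf(
    table_path: str | Path, gene_id: str, per_biospecimen: bool = False
) -> list[ProteinVariant]:
    """Adapter: read a table with standard GDC MAF column names."""
    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#")
    missing = [c for c in GDC_COLUMN_MAP if c not in df.columns]
    if missing:
        raise CohortError(f"{table_path}: missing GDC MAF columns {missing}")
    import tempfile

    lite = df.rename(columns=GDC_COLUMN_MAP)[list(MAF_LITE_COLUMNS)]
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        lite.to_csv(fh, sep="\t", index=False)
        tmp = fh.name
    try:
        return read_maf_lite(tmp, gene_id, per_biospecimen=per_biospecimen)
    finally:
        Path(tmp).unlink(missing_ok=True)


@dataclass(frozen=True)
class ObservedCohort:
    """Validated cohort variants with BLOSUM scores on the missense subset."""

    gene_id: str
    variants: tuple[ProteinVariant, ...]
    missense_scores: tuple[int, ...]
    radical_flags: tuple[bool, ...]

    @property
    def missense(self) -> tuple[ProteinVariant, ...]:
        return tuple(v for v in self.variants if v.kind == "missense")

    @property
    def nonsense_count(self) -> int:
        return sum(1 for v in self.variants if v.kind == "nonsense")

    @property
    def N(self) -> int:
        """Number of observed missense events."""
        return len(self.missense_scores)


def build_cohort(
    gene: GeneModel,
    variants: Sequence[ProteinVariant],
    matrix: SubstitutionMatrix = BLOSUM62,
    radical_threshold: int = RADICAL_THRESHOLD,
    on_mismatch: str = "error",
) -> ObservedCohort:
    """Validate variants against the gene model and score the missense ones.

    ``on_mismatch="skip"`` downgrades wild-type mismatches and out-of-range
    positions to logged skips (public MAFs mix transcript isoforms);
    the default is a hard error.
    """
    if on_mismatch not in ("error", "skip"):
        raise ValueError("on_mismatch must be 'error' or 'skip'")
    kept: list[ProteinVariant] = []
    n_skipped = 0
    for v in variants:
        try:
            kept.append(validate_variant(gene, v))
        except VariantValidationError:
            if on_mismatch == "error":
                raise
            n_skipped += 1
            logger.warning("skipping variant %s: validation failed", v.raw_label)
    if n_skipped:
        logger.warning("%s: skipped %d variants on validation", gene.gene_id, n_skipped)
    scores = tuple(
        matrix.score(v.wt_aa, v.mut_aa) for v in kept if v.kind == "missense"
    )
    flags = tuple(s <= radical_threshold for s in scores)
    return ObservedCohort(
        gene_id=gene.gene_id,
        variants=tuple(kept),
        missense_scores=scores,
        radical_flags=flags,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Observed summary statistics: mu_obs, r_obs and per-domain aggregates.

    ``per_domain`` maps each domain name to ``(count, fraction, mean_score)``
    over the missense variants; fractions sum to 1 and counts to N.
    """

    gene_id: str
    N: int
    mean_score: float
    radical_fraction: float
    nonsense_count: int
    per_domain: dict[str, tuple[int, float, float]]


def summarize(cohort: ObservedCohort, domains: DomainMap) -> CohortSummary:
    """Compute mu_obs (mean missense BLOSUM), r_obs (radical fraction) and
    per-domain counts/fractions/means. Requires at least one missense
    variant; nonsense variants are reported only as a count."""
    if cohort.N == 0:
        raise CohortError(
            f"{cohort.gene_id}: no missense variants; summary statistics "
            "are undefined"
        )
    scores = np.array(cohort.missense_scores, dtype=float)
    flags = np.array(cohort.radical_flags, dtype=bool)
    mu_obs = float(scores.mean())
    r_obs = float(flags.mean())

    per_domain: dict[str, tuple[int, float, float]] = {}
    doms = np.array([assign_domain(domains, v.position) for v in cohort.missense])
    for name in domains.names:
        mask = doms == name
        count = int(mask.sum())
        mean = float(scores[mask].mean()) if count else 0.0
        per_domain[name] = (count, count / cohort.N, mean)
    return CohortSummary(
        gene_id=cohort.gene_id,
        N=cohort.N,
        mean_score=mu_obs,
        radical_fraction=r_obs,
        nonsense_count=cohort.nonsense_count,
        per_domain=per_domain,
    )
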
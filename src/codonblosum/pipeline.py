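"""End-to-end pipeline: load -> enumerate -> summarize -> simulate -> test.

The pipeline reads a CDS FASTA, a MAF-lite cohort table, signature weights
and a domain map, and writes three report tables plus a JSON run manifest:

* ``summary.tsv`` — cohort size, mu_obs/r_obs, neutral mean +/- SD of the
  replicate summaries, and the one-sided p-values (both tails);
* ``gof.tsv`` — chi-square and G goodness-of-fit across domains;
* ``domains.tsv`` — per-domain neutral/observed fractions, enrichment and
  mean BLOSUM scores;
* ``manifest.json`` — seed, M, weights digest and package version, so a
  run can be reproduced bit-for-bit.

Any stage failure is re-raised as :class:`PipelineStageError` naming the
stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .codon_core import DomainMap, GeneModel, load_cds, load_domain_map
from .domain_stats import (
    DomainTable,
    GofResult,
    build_domain_table,
    gof_from_domain_table,
    gof_to_tsv,
)
from .monte_carlo import DEFAULT_M, NeutralTest, ReplicateSet, p_values, simulate
from .neutral_model import (
    NeutralEventTable,
    SubstitutionWeights,
    enumerate_events,
    load_weights,
    neutral_summary,
)
from .observed_cohort import (
    CohortSummary,
    ObservedCohort,
    build_cohort,
    read_maf_lite,
    summarize,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options of one pipeline run.

    ``positions_mode`` selects the neutral event space: ``"observed"``
    restricts to codons mutated in the cohort (the default null for
    selection testing), ``"whole-cds"`` uses every codon.
    """

    fasta: str
    maf: str
    gene_id: str
    weights: str | SubstitutionWeights = "uniform"
    domain_map: str | DomainMap | None = None
    M: int = DEFAULT_M
    seed: int = 0
    positions_mode: str = "observed"
    on_mismatch: str = "error"
    per_biospecimen: bool = False
    add_one: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass(frozen=True)
class PipelineResult:
    gene: GeneModel
    cohort: ObservedCohort
    summary: CohortSummary
    table: NeutralEventTable
    replicates: ReplicateSet
    test: NeutralTest
    domain_table: DomainTable
    gof: GofResult
    manifest: dict


def _resolve_weights(spec: str | SubstitutionWeights) -> SubstitutionWeights:
    if isinstance(spec, SubstitutionWeights):
        return spec
    if spec == "uniform":
        return SubstitutionWeights.uniform()
    if spec == "titv":
        return SubstitutionWeights.titv()
    return load_weights(spec)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis for one gene and optionally write reports.

    Deterministic: identical config and seed produce an identical output
    bundle byte-for-byte.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %-12s done", name)
        return result

    weights = _resolve_weights(config.weights)
    gene = stage("load_cds", load_cds, config.fasta, config.gene_id)
    variants = stage(
        "read_maf", read_maf_lite, config.maf, config.gene_id,
        per_biospecimen=config.per_biospecimen,
    )
    cohort = stage(
        "validate", build_cohort, gene, variants, on_mismatch=config.on_mismatch
    )
    logger.info(
        "cohort: %d missense, %d nonsense events",
        cohort.N,
        cohort.nonsense_count,
    )

    if config.domain_map is None:
        domains = DomainMap(gene_id=config.gene_id, intervals=())
    elif isinstance(config.domain_map, DomainMap):
        domains = config.domain_map
    else:
        domains = stage("domain_map", load_domain_map, config.domain_map, config.gene_id)

    summary = stage("summarize", summarize, cohort, domains)

    if config.positions_mode == "observed":
        positions = {v.position for v in cohort.missense}
    elif config.positions_mode == "whole-cds":
        positions = set(range(1, gene.L + 1))
    else:
        raise PipelineStageError(
            "enumerate", ValueError(f"unknown positions_mode {config.positions_mode!r}")
        )
    table = stage("enumerate", enumerate_events, gene, positions, weights)
    reps = stage("simulate", simulate, table, N=summary.N, M=config.M, seed=config.seed)
    test = stage(
        "p_values", p_values, reps, summary.mean_score, summary.radical_fraction,
        add_one=config.add_one,
    )
    domain_table = stage("domain_table", build_domain_table, table, summary, domains)
    gof = stage("gof", gof_from_domain_table, domain_table)

    manifest = {
        "package": "codonblosum",
        "version": __version__,
        "gene_id": config.gene_id,
        "L": gene.L,
        "N": summary.N,
        "nonsense_count": summary.nonsense_count,
        "M": config.M,
        "seed": config.seed,
        "weights": weights.name,
        "weights_digest": weights.digest(),
        "positions_mode": config.positions_mode,
        "J": table.J,
    }

    result = PipelineResult(
        gene=gene,
        cohort=cohort,
        summary=summary,
        table=table,
        replicates=reps,
        test=test,
        domain_table=domain_table,
        gof=gof,
        manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> None:
    """Write summary.tsv, gof.tsv, domains.tsv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mu_neu, r_neu = neutral_summary(result.table)
    reps = result.replicates
    t = result.test
    lines = [
        "gene\tN\tnonsense\tM\tseed\tmu_obs\tr_obs\tneutral_mu_mean\tneutral_mu_sd"
        "\tneutral_r_mean\tneutral_r_sd\texpected_mu\texpected_r\tp_mean\tp_rad"
        "\tp_mean_opposite\tp_rad_opposite",
        "\t".join(
            [
                result.gene.gene_id,
                str(result.summary.N),
                str(result.summary.nonsense_count),
                str(reps.M),
                str(reps.seed),
                f"{result.summary.mean_score:.3f}",
                f"{result.summary.radical_fraction:.4f}",
                f"{reps.mean_scores.mean():.3f}",
                f"{reps.mean_scores.std(ddof=1):.3f}",
                f"{reps.radical_fractions.mean():.4f}",
                f"{reps.radical_fractions.std(ddof=1):.4f}",
                f"{mu_neu:.3f}",
                f"{r_neu:.4f}",
                f"{t.p_mean:.6f}",
                f"{t.p_rad:.6f}",
                f"{t.p_mean_opposite:.6f}",
                f"{t.p_rad_opposite:.6f}",
            ]
        ),
    ]
    (out / "summary.tsv").write_text("\n".join(lines) + "\n")
    gof_to_tsv({result.gene.gene_id: result.gof}, out / "gof.tsv")
    result.domain_table.to_tsv(out / "domains.tsv")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
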
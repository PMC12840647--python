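"""Synthetic genes and cohorts with controllable selection pressure.

The generator emulates a desk-scale version of a tumour-cohort extraction:
a toy CDS (start codon, no internal STOPs) and a MAF-lite cohort of
protein-change calls. Cohort events are drawn from the gene's *whole-CDS*
neutral event table with per-event probability

    q_j  proportional to  p_j * exp(beta * S_j)

so ``beta = 0`` reproduces the neutral model exactly, ``beta > 0``
up-weights high-BLOSUM (conservative) events — the oncogene-like pattern —
and ``beta < 0`` up-weights radical events — the tumour-suppressor-like
pattern. The exponential tilt is the minimal one-parameter family producing
both regimes; it is a test fixture, not a claim about how selection acts
on real tumours. Nonsense calls are injected at a configurable rate by
sampling STOP-producing single-nucleotide neighbours, exercising the
reader's missense/nonsense handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_core import GeneModel, STOP, translate_codon
from .neutral_model import (
    NeutralEventTable,
    SubstitutionWeights,
    codon_neighbors,
    enumerate_events,
)

_NONSTOP_CODONS = None  # built lazily


def _nonstop_codons() -> list[str]:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        bases = "ACGT"
        _NONSTOP_CODONS = [
            a + b + c
            for a in bases
            for b in bases
            for c in bases
            if translate_codon(a + b + c) != STOP
        ]
    return _NONSTOP_CODONS


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort draw.

    ``selection_beta`` tilts the neutral event distribution on BLOSUM score:
    0 is neutral, positive biases conservative, negative biases radical.
    ``nonsense_rate`` is the expected fraction of nonsense calls added on
    top of the N missense events (default 0.1, the order seen in
    tumour-suppressor cohorts).
    """

    L: int
    N: int
    seed: int
    selection_beta: float = 0.0
    weights: SubstitutionWeights = field(default_factory=SubstitutionWeights.uniform)
    n_cases: int = 100
    nonsense_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0 <= self.nonsense_rate < 1:
            raise ValueError("nonsense_rate must be in [0, 1)")


def make_toy_gene(
    L: int,
    seed: int,
    gene_id: str = "TOYGENE",
    fasta_path: str | Path | None = None,
) -> GeneModel:
    """Random CDS of L codons: ATG start, no internal STOPs, deterministic
    under seed. Optionally written to FASTA (single record, id=gene_id)."""
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(seed)
    pool = _nonstop_codons()
    body = rng.choice(pool, size=L - 1)
    cds = "ATG" + "".join(body)
    gene = GeneModel(gene_id=gene_id, cds=cds)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{gene_id} synthetic toy CDS L={L} seed={seed}\n")
            for i in range(0, len(cds), 60):
                fh.write(cds[i : i + 60] + "\n")
    return gene


def tilt_probabilities(table: NeutralEventTable, beta: float) -> np.ndarray:
    """Selection-tilted event probabilities q_j ∝ p_j exp(beta S_j)."""
    logq = np.log(np.where(table.probs > 0, table.probs, 1.0)) + beta * table.scores
    logq[table.probs == 0] = -np.inf
    q = np.exp(logq - logq[np.isfinite(logq)].max())
    return q / q.sum()


def make_cohort(
    spec: SyntheticSpec,
    gene: GeneModel,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Draw a synthetic MAF-lite cohort table for ``gene``.

    N missense events come from the whole-CDS neutral table tilted by
    ``selection_beta``; nonsense events are added by sampling uniformly
    among STOP-producing single-nucleotide codon neighbours. Case ids are
    assigned at random among ``n_cases`` synthetic cases. Deterministic
    under ``spec.seed``. Returns the table (and writes TSV if asked).
    """
    rng = np.random.default_rng(spec.seed)
    table = enumerate_events(gene, range(1, gene.L + 1), spec.weights)
    q = tilt_probabilities(table, spec.selection_beta)

    picks = rng.choice(table.J, size=spec.N, p=q)
    rows = []
    for j in picks:
        e = table.events[j]
        case = f"CASE{rng.integers(spec.n_cases):04d}"
        rows.append(
            {
                "case_id": case,
                "gene": gene.gene_id,
                "protein_change": f"p.{e.wt_aa}{e.codon_index}{e.mut_aa}",
                "variant_class": "missense",
            }
        )

    n_nonsense = int(rng.binomial(spec.N, spec.nonsense_rate))
    if n_nonsense:
        stop_sites = [
            (i, gene.protein[i - 1])
            for i in range(1, gene.L + 1)
            for (_, _, _, mutant) in codon_neighbors(gene.codons[i - 1])
            if translate_codon(mutant) == STOP
        ]
        for idx in rng.integers(len(stop_sites), size=n_nonsense):
            pos, wt = stop_sites[idx]
            case = f"CASE{rng.integers(spec.n_cases):04d}"
            rows.append(
                {
                    "case_id": case,
                    "gene": gene.gene_id,
                    "protein_change": f"p.{wt}{pos}*",
                    "variant_class": "nonsense",
                }
            )

    df = pd.DataFrame(rows, columns=["case_id", "gene", "protein_change", "variant_class"])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def make_domain_map_intervals(L: int, n_domains: int = 3) -> tuple[tuple[str, int, int], ...]:
    """Deterministic equal-thirds style domain partition for toy genes,
    leaving a gap at each end so the reserved "Other" domain is exercised."""
    if n_domains < 1 or L < 2 * (n_domains + 1):
        raise ValueError("gene too short for that many domains")
    margin = max(1, L // (4 * n_domains))
    span = (L - 2 * margin) // n_domains
    intervals = []
    start = margin + 1
    for d in range(n_domains):
        end = start + span - 1 if d < n_domains - 1 else L - margin
        intervals.append((f"D{d + 1}", start, end))
        start = end + 1
    return tuple(intervals)
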
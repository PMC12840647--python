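"""Domain-level comparison of observed and neutral mutation burden.

For each protein domain d the neutral model assigns a fraction of missense
probability mass, the cohort assigns an observed fraction of events, and
the ratio observed/neutral is the enrichment. Domain-level goodness of fit
uses Pearson's chi-square and the likelihood-ratio G statistic against the
multinomial null given by the neutral fractions (renormalised over the
tested categories so the null is a proper multinomial).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import DomainMap, assign_domain
from .neutral_model import NeutralEventTable
from .observed_cohort import CohortSummary

logger = logging.getLogger(__name__)

# Report print precision, matching common table conventions here:
# fractions 4 d.p., enrichment 2 d.p., mean scores 3 d.p.
FRACTION_DECIMALS = 4
ENRICHMENT_DECIMALS = 2
MEAN_DECIMALS = 3


@dataclass(frozen=True)
class DomainRow:
    """One domain's neutral vs observed burden and severity."""

    domain: str
    neutral_frac: float
    observed_frac: float
    enrichment: float  # NaN when neutral_frac == 0 (undefined)
    neutral_mean_score: float
    observed_mean_score: float
    observed_count: int
    observed_empty: bool  # mean reported as 0 with this flag when count == 0
    flagged: bool  # observed events in a domain with zero neutral mass


@dataclass(frozen=True)
class DomainTable:
    gene_id: str
    rows: tuple[DomainRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path) -> None:
        """Write a report table at print precision (stable across runs)."""
        df = self.to_frame()
        out = pd.DataFrame(
            {
                "domain": df["domain"],
                "neutral_frac": df["neutral_frac"].map(
                    lambda x: f"{x:.{FRACTION_DECIMALS}f}"
                ),
                "observed_frac": df["observed_frac"].map(
                    lambda x: f"{x:.{FRACTION_DECIMALS}f}"
                ),
                "enrichment": df["enrichment"].map(
                    lambda x: "NA" if math.isnan(x) else f"{x:.{ENRICHMENT_DECIMALS}f}"
                ),
                "neutral_mean": df["neutral_mean_score"].map(
                    lambda x: f"{x:.{MEAN_DECIMALS}f}"
                ),
                "observed_mean": df["observed_mean_score"].map(
                    lambda x: f"{x:.{MEAN_DECIMALS}f}"
                ),
                "observed_count": df["observed_count"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


def enrichment_ratio(observed_frac: float, neutral_frac: float) -> float:
    """Observed/neutral fraction ratio; NaN when the neutral fraction is 0
    (undefined null mass) and 0 when nothing was observed."""
    if neutral_frac > 0:
        return observed_frac / neutral_frac
    return math.nan if observed_frac > 0 else math.nan


def build_domain_table(
    table: NeutralEventTable,
    summary: CohortSummary,
    domains: DomainMap,
) -> DomainTable:
    """Aggregate the neutral event table and cohort summary per domain.

    neutral_frac(d) = sum of p_j over events at codons in d;
    neutral_mean(d) = probability-weighted mean BLOSUM within d. Observed
    columns come from the cohort summary. A domain with observed events but
    zero neutral mass is flagged, not an error.
    """
    if table.gene_id != summary.gene_id or table.gene_id != domains.gene_id:
        raise ValueError("neutral table, summary and domain map must share a gene")
    neutral_mass: dict[str, float] = {name: 0.0 for name in domains.names}
    neutral_score_mass: dict[str, float] = {name: 0.0 for name in domains.names}
    for e in table.events:
        d = assign_domain(domains, e.codon_index)
        neutral_mass[d] += e.prob
        neutral_score_mass[d] += e.prob * e.score

    rows = []
    for name in domains.names:
        nf = neutral_mass[name]
        count, of, omean = summary.per_domain.get(name, (0, 0.0, 0.0))
        empty = count == 0
        flagged = nf == 0 and count > 0
        if flagged:
            logger.warning(
                "%s: domain %s has observed events but zero neutral mass",
                table.gene_id,
                name,
            )
        if nf > 0:
            enr = of / nf
            nmean = neutral_score_mass[name] / nf
        else:
            enr = math.nan
            nmean = 0.0
        rows.append(
            DomainRow(
                domain=name,
                neutral_frac=nf,
                observed_frac=of,
                enrichment=enr,
                neutral_mean_score=nmean,
                observed_mean_score=0.0 if empty else omean,
                observed_count=count,
                observed_empty=empty,
                flagged=flagged,
            )
        )
    return DomainTable(gene_id=table.gene_id, rows=tuple(rows))


@dataclass(frozen=True)
class GofResult:
    """Chi-square and likelihood-ratio G goodness-of-fit over k categories."""

    chi2: float
    chi2_p: float
    G: float
    G_p: float
    df: int
    k: int


def goodness_of_fit(
    observed_counts: Sequence[int],
    neutral_probs: Sequence[float],
    N: int | None = None,
) -> GofResult:
    """Goodness of fit of observed domain counts to the neutral multinomial.

    The neutral probabilities are renormalised to sum to 1 over the tested
    categories (logged when the raw probabilities do not). Expected counts
    are E_d = N * prob_d and every E_d must be positive — merge sparse
    categories otherwise. Zero observed counts contribute E_d to chi-square
    and 0 to G (the 0*ln(0) convention). P-values come from the chi-square
    distribution with k - 1 degrees of freedom.
    """
    O = np.asarray(observed_counts, dtype=float)
    probs = np.asarray(neutral_probs, dtype=float)
    if O.shape != probs.shape or O.ndim != 1:
        raise ValueError("observed counts and neutral probs must align 1-d")
    if np.any(O < 0) or np.any(probs < 0):
        raise ValueError("counts and probabilities must be nonnegative")
    n_total = int(O.sum())
    if N is None:
        N = n_total
    if N == 0:
        raise ValueError("N = 0: no observed events to test")
    if n_total != N:
        raise ValueError(f"observed counts sum to {n_total}, expected N={N}")

    total_prob = probs.sum()
    if total_prob <= 0:
        raise ValueError("neutral probabilities sum to zero")
    if not math.isclose(total_prob, 1.0, rel_tol=0, abs_tol=1e-9):
        logger.info(
            "renormalising neutral probabilities (sum %.6f) over %d categories",
            total_prob,
            len(probs),
        )
    probs = probs / total_prob

    E = N * probs
    if np.any(E <= 0):
        bad = [i for i, e in enumerate(E) if e <= 0]
        raise ValueError(
            f"expected count is zero in categories {bad}; merge these "
            "categories before testing"
        )
    chi2 = float(((O - E) ** 2 / E).sum())
    nz = O > 0
    G = float(2.0 * (O[nz] * np.log(O[nz] / E[nz])).sum())
    df = len(O) - 1
    return GofResult(
        chi2=chi2,
        chi2_p=float(stats.chi2.sf(chi2, df)),
        G=G,
        G_p=float(stats.chi2.sf(G, df)),
        df=df,
        k=len(O),
    )


def gof_from_domain_table(domain_table: DomainTable) -> GofResult:
    """Convenience: run the goodness-of-fit test over a domain table's rows,
    dropping domains with zero neutral mass and zero observations."""
    rows = [
        r
        for r in domain_table.rows
        if r.neutral_frac > 0 or r.observed_count > 0
    ]
    return goodness_of_fit(
        [r.observed_count for r in rows],
        [r.neutral_frac for r in rows],
    )


def gof_to_tsv(results: dict[str, GofResult], path) -> None:
    """Write per-gene goodness-of-fit statistics as a TSV report."""
    rows = []
    for gene, r in results.items():
        rows.append(
            {
                "gene": gene,
                "chi2": f"{r.chi2:.4f}",
                "chi2_p": _format_p(r.chi2_p),
                "G": f"{r.G:.4f}",
                "G_p": _format_p(r.G_p),
                "df": r.df,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _format_p(p: float) -> str:
    # scientific notation, "0.0" only at true double-precision underflow
    return "0.0" if p == 0.0 else f"{p:.6e}"
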
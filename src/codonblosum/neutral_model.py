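"""Enumeration of the codon-aware neutral missense event set.

Every codon has exactly 9 single-nucleotide neighbours (3 positions x 3
alternative bases). Neighbours that translate to the same residue
(synonymous) or to STOP (nonsense) are excluded; the survivors form the
neutral event set E. Each event j carries a raw weight w(b->b') from the
base-substitution signature, a probability p_j normalised over the whole
table, a BLOSUM score S_j and a radical flag R_j = 1{S_j <= 0}.

The signature weights summarise the mutational process. The underlying
process for a given cancer cohort is rarely published alongside the cohort,
so weights are configuration: two presets are shipped — ``uniform`` (all 12
substitutions equal) and ``titv`` (transitions kappa times more likely than
transversions, kappa default 2.0) — plus a loader for user-supplied 12-entry
signature files. The presets are generic placeholders, not estimates of any
particular tumour's spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .blosum_scoring import BLOSUM62, RADICAL_THRESHOLD, SubstitutionMatrix
from .codon_core import BASES, STOP, GeneModel, translate_codon

#: The 12 ordered base substitutions b -> b', b != b'.
SUBSTITUTION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (b, bp) for b in BASES for bp in BASES if b != bp
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class WeightsError(ValueError):
    """Raised for incomplete or invalid substitution-weight configurations."""


@dataclass(frozen=True)
class SubstitutionWeights:
    """Nonnegative weights for the 12 single-base substitutions."""

    w: dict[tuple[str, str], float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [p for p in SUBSTITUTION_PAIRS if p not in self.w]
        if missing:
            raise WeightsError(f"missing substitution weights for {missing}")
        extra = [p for p in self.w if p not in SUBSTITUTION_PAIRS]
        if extra:
            raise WeightsError(f"unexpected weight entries {extra}")
        if any(v < 0 for v in self.w.values()):
            raise WeightsError("substitution weights must be nonnegative")
        if all(v == 0 for v in self.w.values()):
            raise WeightsError("at least one substitution weight must be positive")

    @classmethod
    def uniform(cls) -> "SubstitutionWeights":
        """All 12 substitutions equally likely."""
        return cls({p: 1.0 for p in SUBSTITUTION_PAIRS}, name="uniform")

    @classmethod
    def titv(cls, kappa: float = 2.0) -> "SubstitutionWeights":
        """Transition/transversion preset: transitions weighted ``kappa``."""
        if kappa <= 0:
            raise WeightsError("kappa must be positive")
        return cls(
            {p: (kappa if p in _TRANSITIONS else 1.0) for p in SUBSTITUTION_PAIRS},
            name=f"titv(kappa={kappa})",
        )

    def digest(self) -> str:
        """Stable hash of the weight values, for run manifests."""
        import hashlib

        payload = ";".join(
            f"{b}>{bp}:{self.w[(b, bp)]!r}" for b, bp in SUBSTITUTION_PAIRS
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_weights(path: str | Path) -> SubstitutionWeights:
    """Load a 12-entry signature from YAML (``AG: 1.5`` or nested maps) or
    TSV with columns from/to/weight. Completeness is strictly validated."""
    path = Path(path)
    w: dict[tuple[str, str], float] = {}
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise WeightsError(f"weights file {path}: expected a mapping")
        for key, value in data.items():
            if isinstance(value, dict):  # nested {from: {to: weight}}
                for to, weight in value.items():
                    w[(str(key).upper(), str(to).upper())] = float(weight)
            else:  # flat {"AG": weight} or {"A>G": weight}
                k = str(key).upper().replace(">", "").replace("->", "")
                if len(k) != 2:
                    raise WeightsError(f"bad substitution key {key!r}")
                w[(k[0], k[1])] = float(value)
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("from", "to", "weight"):
                if col not in idx:
                    raise WeightsError(f"weights file {path} missing column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                w[(f[idx["from"]].upper(), f[idx["to"]].upper())] = float(
                    f[idx["weight"]]
                )
    return SubstitutionWeights(w, name=path.stem)


@dataclass(frozen=True)
class NeutralEvent:
    """One single-nucleotide missense event in the neutral set E."""

    codon_index: int  # 1-based codon position i
    nt_offset: int  # 1, 2 or 3 within the codon
    from_base: str
    to_base: str
    wt_aa: str
    mut_aa: str
    raw_weight: float  # w(b -> b')
    prob: float  # p_j, normalised over the whole table
    score: int  # BLOSUM score S_j
    radical: bool  # R_j = 1{S_j <= threshold}


@dataclass(frozen=True)
class NeutralEventTable:
    """The neutral event set E for one gene, with normalised probabilities."""

    gene_id: str
    included_positions: frozenset[int]
    events: tuple[NeutralEvent, ...]

    @property
    def J(self) -> int:
        return len(self.events)

    # Cached dense views used by the Monte Carlo sampler.
    @property
    def probs(self) -> np.ndarray:
        return np.array([e.prob for e in self.events], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.events], dtype=float)

    @property
    def radical_flags(self) -> np.ndarray:
        return np.array([e.radical for e in self.events], dtype=bool)


def codon_neighbors(codon: str) -> list[tuple[int, str, str, str]]:
    """All 9 single-nucleotide neighbours of a codon.

    Returns ``(nt_offset, from_base, to_base, mutant_codon)`` tuples; the
    caller partitions them into missense / synonymous / nonsense.
    """
    out = []
    for k in range(3):
        for bp in BASES:
            if bp == codon[k]:
                continue
            mutant = codon[:k] + bp + codon[k + 1 :]
            out.append((k + 1, codon[k], bp, mutant))
    return out


def enumerate_events(
    gene: GeneModel,
    positions: Iterable[int],
    weights: SubstitutionWeights,
    matrix: SubstitutionMatrix = BLOSUM62,
    radical_threshold: int = RADICAL_THRESHOLD,
) -> NeutralEventTable:
    """Build the neutral missense event table over the given codon positions.

    For each included codon all 9 single-nucleotide neighbours are generated;
    synonymous and STOP-producing neighbours are dropped. Probabilities are
    normalised over the whole table (not per codon). Events whose signature
    weight is zero are retained with ``prob = 0`` so the event count J
    depends only on the sequence, not on signature sparsity.
    """
    positions = sorted(set(int(p) for p in positions))
    if not positions:
        raise ValueError("positions must be a nonempty set of codon indices")
    for p in positions:
        if not 1 <= p <= gene.L:
            raise ValueError(f"position {p} outside 1..{gene.L} for {gene.gene_id}")

    raw: list[tuple[int, int, str, str, str, str, float, int]] = []
    for i in positions:
        codon = gene.codons[i - 1]
        wt_aa = gene.protein[i - 1]
        for k, b, bp, mutant in codon_neighbors(codon):
            mut_aa = translate_codon(mutant)
            if mut_aa == wt_aa or mut_aa == STOP:
                continue
            s = matrix.score(wt_aa, mut_aa)
            raw.append((i, k, b, bp, wt_aa, mut_aa, weights.w[(b, bp)], s))

    total = sum(r[6] for r in raw)
    if total <= 0:
        raise WeightsError(
            f"{gene.gene_id}: total raw weight over the event set is zero; "
            "the signature assigns no mass to any missense event here"
        )
    events = tuple(
        NeutralEvent(
            codon_index=i,
            nt_offset=k,
            from_base=b,
            to_base=bp,
            wt_aa=wt,
            mut_aa=mut,
            raw_weight=w,
            prob=w / total,
            score=s,
            radical=s <= radical_threshold,
        )
        for (i, k, b, bp, wt, mut, w, s) in raw
    )
    return NeutralEventTable(
        gene_id=gene.gene_id,
        included_positions=frozenset(positions),
        events=events,
    )


def neutral_summary(table: NeutralEventTable) -> tuple[float, float]:
    """Expected mean BLOSUM score and expected radical fraction under E.

    These are the exact (non-simulated) moments of a single neutral draw:
    ``sum_j p_j S_j`` and ``sum_j p_j R_j``.
    """
    p = table.probs
    return float(p @ table.scores), float(p @ table.radical_flags)
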
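"""BLOSUM62 substitution scoring and the radical-substitution indicator.

The canonical BLOSUM62 half-bit log-odds matrix is vendored below in NCBI
text format so scoring needs no external files. A substitution is called
*radical* when its score is at or below the threshold (default 0,
inclusive): low log-odds means the substitution is rarely tolerated in
conserved protein blocks, i.e. evolutionarily divergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .codon_core import AMINO_ACIDS, STOP

#: Scores at or below this value count as radical (inclusive threshold).
RADICAL_THRESHOLD = 0

# Canonical NCBI BLOSUM62 (Henikoff & Henikoff half-bit log-odds).
_BLOSUM62_TEXT = """\
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X  *
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0 -2 -1  0 -4
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1  0 -1 -4
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3  3  0 -1 -4
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3  4  1 -1 -4
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -3 -3 -2 -4
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2  0  3 -1 -4
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1 -2 -1 -4
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3  0  0 -1 -4
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -3 -3 -1 -4
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -4 -3 -1 -4
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2  0  1 -1 -4
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -3 -1 -1 -4
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -3 -3 -1 -4
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2 -1 -2 -4
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0  0  0 -4
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0 -1 -1  0 -4
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -4 -3 -2 -4
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1 -3 -2 -1 -4
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4 -3 -2 -1 -4
B -2 -1  3  4 -3  0  1 -1  0 -3 -4  0 -3 -3 -2  0 -1 -4 -3 -3  4  1 -1 -4
Z -1  0  0  1 -3  3  4 -2  0 -3 -3  1 -1 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
X  0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1 -1 -1 -4
* -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4  1
"""


class ScoringError(ValueError):
    """Raised for residues outside the standard 20-letter alphabet."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 20 standard residues."""

    name: str
    scores: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if (a, b) not in self.scores:
                    raise ValueError(f"{self.name}: missing entry ({a}, {b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValueError(f"{self.name}: asymmetric at ({a}, {b})")
            if self.scores[(a, a)] <= 0:
                raise ValueError(f"{self.name}: non-positive diagonal at {a}")

    def score(self, wt_aa: str, mut_aa: str) -> int:
        """Score a substitution; STOP and nonstandard residues are errors."""
        for aa in (wt_aa, mut_aa):
            if aa == STOP:
                raise ScoringError("STOP is not scoreable (nonsense excluded)")
            if aa not in AMINO_ACIDS:
                raise ScoringError(f"nonstandard residue {aa!r}")
        return self.scores[(wt_aa, mut_aa)]


def parse_ncbi_matrix(text: str, name: str = "custom") -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix from text.

    Lines starting with ``#`` are comments; the first data line is the
    column header. Only entries for the 20 standard amino acids are kept
    (ambiguity codes B/Z/X and ``*`` columns are ignored).
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    columns = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        fields = line.split()
        row = fields[0]
        if row not in AMINO_ACIDS:
            continue
        for col, value in zip(columns, fields[1:]):
            if col in AMINO_ACIDS:
                scores[(row, col)] = int(value)
    return SubstitutionMatrix(name=name, scores=scores)


def load_matrix_file(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Load an NCBI-format substitution matrix from a file (extension point
    for non-default matrices such as other BLOSUM variants)."""
    path = Path(path)
    return parse_ncbi_matrix(path.read_text(), name=name or path.stem)


BLOSUM62 = parse_ncbi_matrix(_BLOSUM62_TEXT, name="BLOSUM62")


def score(wt_aa: str, mut_aa: str, matrix: SubstitutionMatrix = BLOSUM62) -> int:
    """BLOSUM score of a single amino-acid substitution."""
    return matrix.score(wt_aa, mut_aa)


def is_radical(score_value: int, threshold: int = RADICAL_THRESHOLD) -> bool:
    """Whether a substitution score counts as radical: ``score <= threshold``.

    The indicator is inclusive at the threshold, so a score of exactly 0 is
    radical under the default.
    """
    return score_value <= threshold
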
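"""Coding-sequence bookkeeping: codons, translation, protein variants, domains.

Everything downstream works in 1-based codon/residue coordinates with closed
domain intervals, matching HGVSp convention. The standard genetic code (NCBI
table 1) is the only code supported; a terminal STOP codon on a CDS is
stripped, an internal STOP is a hard error because the wild-type protein is
then undefined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData

STOP = "*"
BASES = "ACGT"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, STOP codons mapped to "*"
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: STOP for c in _STANDARD_TABLE.stop_codons})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}
_THREE_TO_ONE["TER"] = STOP
_ONE_TO_THREE = {v: k for k, v in IUPACData.protein_letters_3to1.items()}
_ONE_TO_THREE[STOP] = "Ter"


class CdsError(ValueError):
    """Raised when a coding sequence violates the CDS contract."""


class HgvspParseError(ValueError):
    """Raised when a protein-change label cannot be parsed."""


class SynonymousVariantError(HgvspParseError):
    """Raised for labels where the stated WT and mutant residues coincide."""


class VariantValidationError(ValueError):
    """Raised when a parsed variant disagrees with the gene model."""


def translate_codon(codon: str) -> str:
    """Translate a single codon under the standard genetic code.

    Returns a one-letter amino acid, or ``"*"`` for a STOP codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CdsError(f"invalid codon {codon!r}: expected three bases from ACGT")
    return GENETIC_CODE[codon]


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding sequence split into codons with its translation.

    Attributes
    ----------
    gene_id : str
        Identifier used to match FASTA records and cohort rows.
    cds : str
        Coding sequence over {A,C,G,T}, length ``3 * L``, terminal STOP
        codon already removed.
    codons : tuple of str
        The L codons ``c_1 .. c_L``.
    protein : tuple of str
        One-letter translation ``a_i = T(c_i)``; never contains STOP.
    had_terminal_stop : bool
        Whether the input sequence ended in a STOP codon that was stripped.
    """

    gene_id: str
    cds: str
    codons: tuple[str, ...] = field(init=False)
    protein: tuple[str, ...] = field(init=False)
    had_terminal_stop: bool = False

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        if len(cds) % 3 != 0:
            raise CdsError(
                f"{self.gene_id}: CDS length {len(cds)} is not divisible by 3"
            )
        bad = set(cds) - set(BASES)
        if bad:
            raise CdsError(f"{self.gene_id}: non-ACGT characters {sorted(bad)}")
        if not cds:
            raise CdsError(f"{self.gene_id}: empty CDS")
        codons = tuple(cds[i : i + 3] for i in range(0, len(cds), 3))
        protein = tuple(GENETIC_CODE[c] for c in codons)
        for i, aa in enumerate(protein, start=1):
            if aa == STOP:
                raise CdsError(
                    f"{self.gene_id}: internal STOP codon {codons[i - 1]} "
                    f"at codon index {i}"
                )
        object.__setattr__(self, "cds", cds)
        object.__setattr__(self, "codons", codons)
        object.__setattr__(self, "protein", protein)

    @property
    def L(self) -> int:
        """Number of codons (terminal STOP excluded)."""
        return len(self.codons)


def load_cds(
    fasta_path: str | Path,
    gene_id: str,
    protein_fasta: str | Path | None = None,
) -> GeneModel:
    """Load a coding sequence for ``gene_id`` from a FASTA file.

    The record whose id matches ``gene_id`` (exactly, or as a ``|``-separated
    field) is selected. ``U`` is normalised to ``T``. A terminal STOP codon
    is stripped and recorded; internal STOPs, non-ACGT characters and lengths
    not divisible by 3 are hard errors.

    If ``protein_fasta`` is given, the translated CDS is cross-checked
    against the matching protein record and a mismatch is an error.
    """
    record = _select_record(fasta_path, gene_id)
    seq = str(record.seq).upper().replace("U", "T")
    had_stop = False
    if len(seq) >= 3 and len(seq) % 3 == 0 and GENETIC_CODE.get(seq[-3:]) == STOP:
        seq = seq[:-3]
        had_stop = True
    gene = GeneModel(gene_id=gene_id, cds=seq, had_terminal_stop=had_stop)
    if protein_fasta is not None:
        prot = str(_select_record(protein_fasta, gene_id).seq).upper().rstrip(STOP)
        if "".join(gene.protein) != prot:
            raise CdsError(
                f"{gene_id}: CDS translation does not match the supplied "
                f"protein FASTA (lengths {gene.L} vs {len(prot)})"
            )
    return gene


def _select_record(fasta_path: str | Path, gene_id: str):
    matches = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id == gene_id or gene_id in rec.id.split("|"):
            matches.append(rec)
    if not matches:
        raise CdsError(f"no FASTA record with id {gene_id!r} in {fasta_path}")
    if len(matches) > 1:
        raise CdsError(f"multiple FASTA records match {gene_id!r} in {fasta_path}")
    return matches[0]


# ---------------------------------------------------------------------------
# Protein variants (HGVSp-style labels)
# ---------------------------------------------------------------------------

_AA1 = "[ACDEFGHIKLMNPQRSTVWY]"
_AA3 = "|".join(sorted(_THREE_TO_ONE, key=len, reverse=True))
_HGVSP_RE = re.compile(
    rf"^(?:p\.)?"
    rf"(?P<wt>{_AA1}|(?i:{_AA3}))"
    rf"(?P<pos>[1-9][0-9]*)"
    rf"(?P<mut>{_AA1}|\*|(?i:{_AA3}))$"
)


@dataclass(frozen=True)
class ProteinVariant:
    """A protein-level substitution call for one case.

    ``kind`` is ``"nonsense"`` exactly when ``mut_aa`` is the STOP symbol;
    missense variants always have ``mut_aa != wt_aa`` and no STOP.
    """

    case_id: str
    gene_id: str
    position: int
    wt_aa: str
    mut_aa: str
    kind: str
    raw_label: str

    def __post_init__(self) -> None:
        if self.kind not in ("missense", "nonsense"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if (self.kind == "nonsense") != (self.mut_aa == STOP):
            raise ValueError("kind=nonsense iff mut_aa is STOP")
        if self.kind == "missense" and self.mut_aa == self.wt_aa:
            raise ValueError("missense variant with identical residues")


def _residue_to_one(token: str) -> str:
    token = token.upper()
    if len(token) == 1:
        return token
    try:
        return _THREE_TO_ONE[token]
    except KeyError:  # pragma: no cover - excluded by the regex
        raise HgvspParseError(f"unknown residue code {token!r}") from None


def parse_hgvsp(
    label: str, case_id: str = "", gene_id: str = ""
) -> ProteinVariant:
    """Parse an HGVSp-style substitution label like ``p.R273H`` or ``Q136*``.

    Accepts an optional ``p.`` prefix and one- or three-letter residue codes
    (``*``/``Ter`` denote STOP). Synonymous labels are rejected with
    :class:`SynonymousVariantError`; anything unparseable raises
    :class:`HgvspParseError` carrying the raw string.
    """
    m = _HGVSP_RE.match(label.strip())
    if m is None:
        raise HgvspParseError(f"cannot parse protein change label {label!r}")
    wt = _residue_to_one(m.group("wt"))
    mut = STOP if m.group("mut") == STOP else _residue_to_one(m.group("mut"))
    if wt == mut:
        raise SynonymousVariantError(f"synonymous label {label!r} (wt == mut)")
    pos = int(m.group("pos"))
    kind = "nonsense" if mut == STOP else "missense"
    return ProteinVariant(
        case_id=case_id,
        gene_id=gene_id,
        position=pos,
        wt_aa=wt,
        mut_aa=mut,
        kind=kind,
        raw_label=label.strip(),
    )


def format_hgvsp(variant: ProteinVariant, three_letter: bool = False) -> str:
    """Render a variant back to an HGVSp-style label with a ``p.`` prefix."""
    if three_letter:
        wt = _ONE_TO_THREE[variant.wt_aa]
        mut = _ONE_TO_THREE[variant.mut_aa]
    else:
        wt, mut = variant.wt_aa, variant.mut_aa
    return f"p.{wt}{variant.position}{mut}"


def validate_variant(gene: GeneModel, variant: ProteinVariant) -> ProteinVariant:
    """Check a variant against the gene model and return it unchanged.

    The stated wild-type residue must match the translated CDS at the stated
    position; otherwise a :class:`VariantValidationError` names the expected
    and stated residues. Callers processing whole cohorts may downgrade the
    mismatch to a logged skip (public MAFs mix transcript isoforms).
    """
    if not 1 <= variant.position <= gene.L:
        raise VariantValidationError(
            f"{variant.raw_label or variant}: position {variant.position} "
            f"out of range 1..{gene.L} for {gene.gene_id}"
        )
    expected = gene.protein[variant.position - 1]
    if expected != variant.wt_aa:
        raise VariantValidationError(
            f"{variant.raw_label or variant}: wild-type mismatch at codon "
            f"{variant.position} of {gene.gene_id}: CDS has {expected}, "
            f"label states {variant.wt_aa}"
        )
    return variant


# ---------------------------------------------------------------------------
# Protein domain maps
# ---------------------------------------------------------------------------

OTHER_DOMAIN = "Other"


@dataclass(frozen=True)
class DomainMap:
    """Non-overlapping closed residue intervals naming protein domains.

    Residues not covered by any interval belong to the reserved domain
    ``"Other"``.
    """

    gene_id: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple(
            (str(name), int(start), int(end)) for name, start, end in self.intervals
        )
        for name, start, end in ivs:
            if name == OTHER_DOMAIN:
                raise ValueError(f"{OTHER_DOMAIN!r} is reserved for uncovered residues")
            if start < 1 or end < start:
                raise ValueError(f"bad interval {name} [{start}, {end}]")
        ordered = sorted(ivs, key=lambda iv: iv[1])
        for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"domains {n1} and {n2} overlap")
        object.__setattr__(self, "intervals", tuple(ordered))

    @property
    def names(self) -> tuple[str, ...]:
        """Domain names in sequence order, with ``"Other"`` appended."""
        return tuple(n for n, _, _ in self.intervals) + (OTHER_DOMAIN,)


def assign_domain(domain_map: DomainMap, position: int) -> str:
    """Return the domain covering a 1-based residue position, else "Other"."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for name, start, end in domain_map.intervals:
        if start <= position <= end:
            return name
    return OTHER_DOMAIN


def load_domain_map(path: str | Path, gene_id: str) -> DomainMap:
    """Read a domain map from YAML or TSV.

    TSV columns: gene_id, domain, start, end (1-based inclusive). YAML: a
    mapping ``gene_id -> [{domain, start, end}, ...]`` or a flat list of the
    same records each carrying a ``gene_id`` key.
    """
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if isinstance(data, dict):
            records = data.get(gene_id, [])
        else:
            records = [r for r in data if r.get("gene_id") == gene_id]
        for r in records:
            rows.append((r["domain"], int(r["start"]), int(r["end"])))
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {col: i for i, col in enumerate(header)}
            for col in ("gene_id", "domain", "start", "end"):
                if col not in idx:
                    raise ValueError(f"domain map {path} missing column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if f[idx["gene_id"]] != gene_id:
                    continue
                rows.append((f[idx["domain"]], int(f[idx["start"]]), int(f[idx["end"]])))
    return DomainMap(gene_id=gene_id, intervals=tuple(rows))
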
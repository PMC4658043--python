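"""MAPKKK family identification and Raf/MEKK/ZIK subfamily classification.

Family membership is decided by a homology-threshold rule: a candidate
protein is a MAPKKK when at least ``min_hits`` distinct query proteins
(known MAPKKKs from reference species) each align to it locally with more
than ``identity_threshold`` identity over a substantial span.  Subfamilies
are assigned by scanning for degenerate kinase-domain signature motifs:

* ZIK  — ``GTPEFMAPE(L/V)(Y/F)``
* MEKK — ``G(T/S)Px(W/F)MAPEV``
* Raf  — ``GTxx(W/Y)MAPE``

Patterns combine fixed residues, ``x`` wildcards, and parenthesised
alternative residue sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# -------------------------------------------------------------- motifs


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate amino-acid pattern: fixed residues, wildcards ('x'),
    and alternative residue sets, with a subfamily label."""

    elements: tuple[frozenset[str] | None, ...]  # None = wildcard
    label: str

    def __len__(self) -> int:
        return len(self.elements)

    def to_text(self) -> str:
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("x")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("(" + "/".join(sorted(el)) + ")")
        return "".join(parts)


class MotifParseError(ValueError):
    pass


def parse_motif_pattern(text: str, label: str = "") -> MotifPattern:
    """Parse a degenerate motif string such as ``"G(T/S)Px(W/F)MAPEV"``.

    Uppercase letters are fixed residues, ``x``/``X`` is a wildcard, and
    ``(A/B/...)`` is an alternative residue set.  Whitespace is ignored.
    Raises :class:`MotifParseError` naming the offending position for
    unbalanced parentheses, empty alternatives, or non-residue characters.
    """
    elements: list[frozenset[str] | None] = []
    stripped = [(i, ch) for i, ch in enumerate(text) if not ch.isspace()]
    i = 0
    while i < len(stripped):
        pos, ch = stripped[i]
        if ch in ("x", "X"):
            elements.append(None)
            i += 1
        elif ch == "(":
            j = i + 1
            alts: list[str] = []
            expect_residue = True
            closed = False
            while j < len(stripped):
                p, c = stripped[j]
                if c == ")":
                    closed = True
                    break
                if expect_residue:
                    if c.upper() not in CANONICAL_RESIDUES:
                        raise MotifParseError(
                            f"expected residue at position {p}, got {c!r}"
                        )
                    alts.append(c.upper())
                    expect_residue = False
                else:
                    if c != "/":
                        raise MotifParseError(
                            f"expected '/' or ')' at position {p}, got {c!r}"
                        )
                    expect_residue = True
                j += 1
            if not closed:
                raise MotifParseError(f"unbalanced parenthesis at position {pos}")
            if not alts or expect_residue:
                raise MotifParseError(f"empty alternative at position {pos}")
            elements.append(frozenset(alts))
            i = j + 1
        elif ch == ")":
            raise MotifParseError(f"unbalanced parenthesis at position {pos}")
        elif ch.upper() in CANONICAL_RESIDUES:
            elements.append(frozenset(ch.upper()))
            i += 1
        else:
            raise MotifParseError(f"non-residue character {ch!r} at position {pos}")
    return MotifPattern(tuple(elements), label)


#: Signature motifs of the three maize MAPKKK subfamilies.
SUBFAMILY_PATTERNS: tuple[MotifPattern, ...] = (
    parse_motif_pattern("GTPEFMAPE(L/V)(Y/F)", label="ZIK"),
    parse_motif_pattern("G(T/S)Px(W/F)MAPEV", label="MEKK"),
    parse_motif_pattern("GTxx(W/Y)MAPE", label="Raf"),
)


def scan_motif(sequence: str, pattern: MotifPattern) -> list[int]:
    """All (possibly overlapping) 0-based offsets where *pattern* matches."""
    seq = sequence.upper()
    k = len(pattern)
    hits = []
    for start in range(len(seq) - k + 1):
        ok = True
        for el, ch in zip(pattern.elements, seq[start : start + k]):
            if el is not None and ch not in el:
                ok = False
                break
        if ok:
            hits.append(start)
    return hits


def classify_subfamily(
    sequence: str, patterns: Sequence[MotifPattern] = SUBFAMILY_PATTERNS
) -> set[str]:
    """Set of subfamily labels whose signature motif occurs at least once;
    an empty set means unclassified."""
    return {p.label for p in patterns if scan_motif(sequence, p)}


# ------------------------------------------------- pairwise identity

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_identity(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, int]:
    """Optimal local-alignment identity and aligned span.

    Smith-Waterman with BLOSUM62 and affine gaps (first gap residue scores
    ``gap_open``, each further residue ``gap_extend``).  Identity is
    identical residue pairs divided by the alignment length with gaps in
    the denominator.  When no positive-scoring alignment exists the empty
    alignment is optimal and identity is 0 over span 0.  Arguments are
    ordered canonically so the result is symmetric even when co-optimal
    alignments differ.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if b < a:
        a, b = b, a
    aligner = _make_aligner(gap_open, gap_extend)
    if aligner.score(a, b) <= 0:
        return 0.0, 0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    span = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / span, span


def pairwise_identity(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Identity fraction of the optimal local alignment of *a* and *b*."""
    return align_identity(a, b, gap_open, gap_extend)[0]


# --------------------------------------------------- family calling


@dataclass(frozen=True)
class FamilyCallParams:
    """Homology-threshold rule parameters.

    identity_threshold
        Minimum (strict) span identity a query alignment must exceed.
    min_hits
        Minimum (inclusive) number of distinct qualifying queries.
    min_coverage
        Minimum fraction of the shorter sequence the qualifying alignment
        must cover; excludes high-identity micro-alignments between
        unrelated sequences.
    """

    identity_threshold: float = 0.25
    min_hits: int = 5
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")


@dataclass
class FamilyAssignment:
    candidate_id: str
    qualifying_hit_count: int
    is_member: bool
    subfamilies: set[str] = field(default_factory=set)
    chromosome: str = "unknown"


def identify_family(
    candidates: Mapping[str, str],
    queries: Mapping[str, str],
    params: FamilyCallParams = FamilyCallParams(),
    patterns: Sequence[MotifPattern] = SUBFAMILY_PATTERNS,
    chromosomes: Mapping[str, str] | None = None,
) -> list[FamilyAssignment]:
    """Call family membership for each candidate against the query panel.

    A query qualifies when its optimal local alignment with the candidate
    exceeds the identity threshold and covers at least ``min_coverage`` of
    the shorter sequence; the candidate is a member when at least
    ``min_hits`` distinct queries qualify.  Members are also motif-scanned
    for subfamily labels.  Output preserves candidate input order.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    chromosomes = chromosomes or {}
    out = []
    for cid, cseq in candidates.items():
        hits = 0
        for qseq in queries.values():
            ident, span = align_identity(cseq, qseq)
            if ident > params.identity_threshold and span >= params.min_coverage * min(
                len(cseq), len(qseq)
            ):
                hits += 1
        member = hits >= params.min_hits
        out.append(
            FamilyAssignment(
                candidate_id=cid,
                qualifying_hit_count=hits,
                is_member=member,
                subfamilies=classify_subfamily(cseq, patterns) if member else set(),
                chromosome=chromosomes.get(cid, "unknown"),
            )
        )
    return out


def chromosome_distribution(assignments: Iterable[FamilyAssignment]) -> dict[str, int]:
    """Member counts per chromosome label (including ``"unknown"``)."""
    return dict(Counter(a.chromosome for a in assignments if a.is_member))


# ------------------------------------------------------------- FASTA io


def read_fasta(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read protein FASTA; returns (id -> sequence, id -> chromosome).

    Chromosome labels come from a ``chrom=`` key on the description line
    when present, else ``"unknown"``.
    """
    seqs: dict[str, str] = {}
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        chroms[rec.id] = "unknown"
        for tok in rec.description.split():
            if tok.startswith("chrom="):
                chroms[rec.id] = tok[len("chrom=") :]
    return seqs, chroms


def write_fasta(path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
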
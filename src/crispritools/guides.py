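"""CRISPRi spacer screening: exhaustive off-target scanning and NT spacer design.

A 20-nt spacer is compared by Hamming distance against every genomic
20-mer that is immediately 5' of a PAM (NGG for SpCas9) on either strand;
candidate spacers with any off-target site at four or fewer mismatches
are discarded.  Non-targeting (NT) spacers are drawn at exactly 50% GC
and accepted only if their genome-wide minimum mismatch count is at
least five.

Conventions: the PAM is the 3 nt immediately 3' of the protospacer on
the protospacer strand; positions are 0-based starts of the protospacer
on the forward strand; ambiguous bases (N etc.) count as mismatches and
never satisfy a PAM letter; genomes are treated as linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "Spacer",
    "OffTargetHit",
    "scan_offtargets",
    "passes_offtarget_filter",
    "generate_nt_spacer",
    "min_mismatch",
    "NO_SITE_SENTINEL",
]

SPACER_LENGTH = 20
PAM_LENGTH = 3
#: Returned by :func:`min_mismatch` when the genome has no PAM-adjacent site.
NO_SITE_SENTINEL = SPACER_LENGTH + 1

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _as_contigs(genome) -> dict:
    if isinstance(genome, str):
        return {"contig_1": genome}
    if isinstance(genome, dict):
        return {str(k): str(v) for k, v in genome.items()}
    # sequence of (name, seq) pairs or of SeqRecord-likes
    out = {}
    for item in genome:
        if isinstance(item, tuple):
            out[str(item[0])] = str(item[1])
        else:
            out[str(item.id)] = str(item.seq)
    return out


@dataclass
class Spacer:
    """A 20-nt gRNA spacer, optionally annotated with its intended site."""

    name: str
    sequence: str
    intended_site: tuple | None = None  # (contig, position, strand)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) != SPACER_LENGTH:
            raise ValueError(
                f"spacer {self.name!r}: length {len(self.sequence)} != {SPACER_LENGTH}"
            )
        if any(b not in "ACGT" for b in self.sequence):
            raise ValueError(f"spacer {self.name!r}: non-ACGT characters")

    @property
    def gc_fraction(self) -> float:
        return sum(b in "GC" for b in self.sequence) / SPACER_LENGTH


@dataclass
class OffTargetHit:
    contig: str
    position: int  # 0-based start of the protospacer on the forward strand
    strand: str  # "+" or "-"
    mismatches: int
    pam: str  # 3 nt on the protospacer strand

    def site(self) -> tuple:
        return (self.contig, self.position, self.strand)


def _pam_ok(pam_codes: np.ndarray, pam_motif: str) -> np.ndarray:
    """Boolean per window: PAM triplet matches the motif (N = any ACGT)."""
    ok = np.ones(pam_codes.shape[0], dtype=bool)
    for k, letter in enumerate(pam_motif):
        col = pam_codes[:, k]
        if letter == "N":
            ok &= col != 255
        else:
            ok &= col == _ENCODE[ord(letter)]
    return ok


def _windows(codes: np.ndarray, width: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(codes, width)


def _scan_one_strand(codes: np.ndarray, spacer_codes: np.ndarray, pam_motif: str):
    """(positions, mismatches) of PAM-adjacent protospacers along *codes*."""
    n = codes.size
    total = SPACER_LENGTH + PAM_LENGTH
    if n < total:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    proto = _windows(codes, SPACER_LENGTH)[: n - total + 1]
    pam = _windows(codes, PAM_LENGTH)[SPACER_LENGTH:]
    ok = _pam_ok(pam, pam_motif)
    # ambiguous bases never match the spacer
    mism = (proto != spacer_codes[None, :]).sum(axis=1)
    pos = np.nonzero(ok)[0]
    return pos, mism[pos]


def _spacer_sequence(spacer) -> str:
    return spacer.sequence if isinstance(spacer, Spacer) else str(spacer).upper()


def scan_offtargets(
    spacer,
    genome,
    max_mismatches: int = 4,
    pam_motif: str = "NGG",
) -> list:
    """All PAM-adjacent genomic sites within ``max_mismatches`` of the spacer.

    Both strands of every contig are scanned; hits are sorted by
    (contig, position, strand).  *spacer* may be a :class:`Spacer` or a
    raw 20-nt string; *genome* a string, dict of contigs, list of
    (name, seq) pairs or of SeqRecords.
    """
    seq = _spacer_sequence(spacer)
    if len(seq) != SPACER_LENGTH or any(b not in "ACGT" for b in seq):
        raise ValueError("spacer must be a 20-nt ACGT sequence")
    sp = _encode(seq)
    hits = []
    for contig, contig_seq in _as_contigs(genome).items():
        fwd = _encode(contig_seq.upper())
        n = fwd.size
        pos, mism = _scan_one_strand(fwd, sp, pam_motif)
        for p, m in zip(pos, mism):
            if m <= max_mismatches:
                pam = contig_seq[p + SPACER_LENGTH : p + SPACER_LENGTH + PAM_LENGTH]
                hits.append(OffTargetHit(contig, int(p), "+", int(m), pam.upper()))
        rc_seq = str(Seq(contig_seq).reverse_complement()).upper()
        rc = _encode(rc_seq)
        pos, mism = _scan_one_strand(rc, sp, pam_motif)
        for p, m in zip(pos, mism):
            if m <= max_mismatches:
                pam = rc_seq[p + SPACER_LENGTH : p + SPACER_LENGTH + PAM_LENGTH]
                fwd_start = n - (int(p) + SPACER_LENGTH)
                hits.append(OffTargetHit(contig, fwd_start, "-", int(m), pam))
    hits.sort(key=lambda h: (h.contig, h.position, h.strand))
    return hits


def passes_offtarget_filter(
    spacer,
    genome,
    max_mismatches: int = 4,
    pam_motif: str = "NGG",
) -> bool:
    """False (discard) iff any site *other than the intended one* has
    ``max_mismatches`` (default 4) or fewer mismatches."""
    intended = spacer.intended_site if isinstance(spacer, Spacer) else None
    for hit in scan_offtargets(spacer, genome, max_mismatches, pam_motif):
        if intended is not None and hit.site() == tuple(intended):
            continue
        return False
    return True


def min_mismatch(spacer, genome, pam_motif: str = "NGG") -> int:
    """Genome-wide minimum Hamming distance to any PAM-adjacent 20-mer.

    Returns :data:`NO_SITE_SENTINEL` (21) if no PAM-adjacent site exists.
    """
    seq = _spacer_sequence(spacer)
    if len(seq) != SPACER_LENGTH or any(b not in "ACGT" for b in seq):
        raise ValueError("spacer must be a 20-nt ACGT sequence")
    sp = _encode(seq)
    best = NO_SITE_SENTINEL
    for contig_seq in _as_contigs(genome).values():
        for s in (contig_seq.upper(), str(Seq(contig_seq).reverse_complement()).upper()):
            _, mism = _scan_one_strand(_encode(s), sp, pam_motif)
            if mism.size:
                best = min(best, int(mism.min()))
    return best


def generate_nt_spacer(
    genome,
    seed: int = 0,
    n_candidates: int = 1000,
    min_distance: int = 5,
    pam_motif: str = "NGG",
) -> Spacer:
    """Draw a non-targeting spacer: exactly 50% GC, >= *min_distance*
    mismatches to every PAM-adjacent genomic 20-mer.

    Rejection-samples random 20-mers with exactly 10 G/C bases until one
    clears the genome-wide mismatch floor; deterministic given *seed*.
    Raises (reporting the best distance achieved) if no candidate within
    ``n_candidates`` qualifies.
    """
    rng = np.random.default_rng(seed)
    best = -1
    for _ in range(n_candidates):
        bases = np.empty(SPACER_LENGTH, dtype="<U1")
        gc_pos = rng.choice(SPACER_LENGTH, size=SPACER_LENGTH // 2, replace=False)
        at = np.ones(SPACER_LENGTH, dtype=bool)
        at[gc_pos] = False
        bases[gc_pos] = np.array(["G", "C"])[rng.integers(0, 2, gc_pos.size)]
        bases[at] = np.array(["A", "T"])[rng.integers(0, 2, int(at.sum()))]
        seq = "".join(bases)
        d = min_mismatch(seq, genome, pam_motif)
        if d >= min_distance:
            return Spacer(name="NT", sequence=seq)
        best = max(best, d)
    raise RuntimeError(
        f"no non-targeting spacer found in {n_candidates} candidates "
        f"(best genome-wide distance achieved: {best})"
    )
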
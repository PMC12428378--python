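"""Alpha-satellite monomer extraction.

A 171 bp consensus monomer is located across the genome in both
orientations; semi-global alignments with >= `min_identity` identity are
retained, overlaps are resolved greedily by identity, monomers overlapping
assembly N-gaps are excluded, and tandem runs of hits are grouped into
arrays.

Candidate placements come from exact k-mer seeding (k=12).  A monomer that
passes the 95% identity threshold carries at most 8 mismatches over 171 bp,
which always leaves a clean stretch of at least 19 bp, so every retainable
monomer is guaranteed to produce at least one exact 12-mer seed; no separate
tandem-extension step is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .align import cigar_columns, infix_hit, revcomp
from .seqio import GenomeSequence, read_fasta

__all__ = [
    "ConsensusMonomer",
    "MonomerHit",
    "MonomerArray",
    "default_consensus",
    "load_consensus",
    "scan_monomers",
    "filter_gap_overlaps",
    "segment_arrays",
]

MIN_MONOMER_LEN = 150
MAX_MONOMER_LEN = 200
_SEED_K = 12
_WINDOW_PAD = 16


@dataclass(frozen=True)
class ConsensusMonomer:
    """The ~171 bp consensus monomer against which monomers are called."""

    sequence: str

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not MIN_MONOMER_LEN <= n <= MAX_MONOMER_LEN:
            raise ValueError(f"consensus length {n} outside [{MIN_MONOMER_LEN}, {MAX_MONOMER_LEN}]")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("consensus must contain only A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MonomerHit:
    """One extracted monomer: genomic interval, strand, oriented sequence, identity."""

    seq_name: str
    start: int
    end: int
    strand: str
    oriented_seq: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MonomerArray:
    """A tandem run of monomer hits separated by at most `max_join_gap` bp."""

    hits: list[MonomerHit]
    seq_name: str = ""
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.hits:
            self.seq_name = self.hits[0].seq_name
            strands = {h.strand for h in self.hits}
            self.orientation = strands.pop() if len(strands) == 1 else "mixed"

    @property
    def array_start(self) -> int:
        return self.hits[0].start

    @property
    def array_end(self) -> int:
        return self.hits[-1].end

    def __len__(self) -> int:
        return len(self.hits)


def default_consensus() -> ConsensusMonomer:
    """The shipped synthetic 171 bp consensus (stand-in for a published one)."""
    ref = resources.files("horscan.data") / "synthetic_alpha_consensus.fasta"
    with resources.as_file(ref) as path:
        return load_consensus(path)


def load_consensus(path: str | Path) -> ConsensusMonomer:
    recs = read_fasta(path)
    return ConsensusMonomer(recs[0].bases)


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(bases: str) -> np.ndarray:
    return _ENC[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes and a validity mask (no N inside window)."""
    if len(enc) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = ~(win == 255).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = (win.astype(np.int64) * powers).sum(axis=1)
    return codes, valid


def _candidate_starts(bases: str, consensus_oriented: str, k: int = _SEED_K) -> np.ndarray:
    """Distinct candidate monomer start positions from exact k-mer seed matches."""
    enc_g = _encode(bases)
    enc_c = _encode(consensus_oriented)
    g_codes, g_valid = _kmer_codes(enc_g, k)
    c_codes, c_valid = _kmer_codes(enc_c, k)
    c_codes = c_codes[c_valid]
    c_offsets = np.nonzero(c_valid)[0]
    if len(g_codes) == 0 or len(c_codes) == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(c_codes, kind="stable")
    sc = c_codes[order]
    so = c_offsets[order]
    pos = np.nonzero(g_valid & np.isin(g_codes, sc))[0]
    if len(pos) == 0:
        return np.empty(0, dtype=np.int64)
    gl = np.searchsorted(sc, g_codes[pos], side="left")
    gr = np.searchsorted(sc, g_codes[pos], side="right")
    counts = gr - gl
    rep_pos = np.repeat(pos, counts)
    cum = np.concatenate(([0], np.cumsum(counts)))
    j = np.arange(counts.sum()) - np.repeat(cum[:-1], counts) + np.repeat(gl, counts)
    starts = rep_pos - so[j]
    starts = np.unique(starts)
    return starts[(starts > -_WINDOW_PAD) & (starts < len(bases) - MIN_MONOMER_LEN + _WINDOW_PAD)]


def _hits_from_candidates(
    seq: GenomeSequence,
    starts: Iterable[int],
    consensus: ConsensusMonomer,
    strand: str,
    min_identity: float,
) -> dict[tuple[int, int, str], MonomerHit]:
    cons = consensus.sequence if strand == "+" else revcomp(consensus.sequence)
    L = len(cons)
    n = seq.length
    out: dict[tuple[int, int, str], MonomerHit] = {}
    for s in starts:
        w0 = max(int(s) - _WINDOW_PAD, 0)
        w1 = min(int(s) + L + _WINDOW_PAD, n)
        if w1 - w0 < MIN_MONOMER_LEN:
            continue
        a, b, ident = infix_hit(cons, seq.bases[w0:w1])
        start, end = w0 + a, w0 + b
        if ident < min_identity or not MIN_MONOMER_LEN <= end - start <= MAX_MONOMER_LEN:
            continue
        key = (start, end, strand)
        if key in out and out[key].identity >= ident:
            continue
        segment = seq.bases[start:end]
        oriented = segment if strand == "+" else revcomp(segment)
        out[key] = MonomerHit(seq.name, start, end, strand, oriented, ident)
    return out


_BOUNDARY_TOL = 10


def _greedy_tile(
    hits: Sequence[MonomerHit],
    seq: GenomeSequence,
    consensus: ConsensusMonomer,
    min_identity: float,
) -> list[MonomerHit]:
    """Resolve overlaps: higher identity wins, then leftmost start, '+' first.

    Tandem neighbours produce co-optimal alignments whose boundaries jitter
    by a few bases; a lower-ranked hit overlapping an accepted one by at
    most `_BOUNDARY_TOL` bp per side is trimmed back to the uncovered
    interval (identity recomputed) rather than discarded.
    """
    covered = np.zeros(seq.length, dtype=bool)
    accepted: list[MonomerHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, h.start, h.end, h.strand)):
        region = covered[h.start : h.end]
        if not region.any():
            covered[h.start : h.end] = True
            accepted.append(h)
            continue
        free = np.nonzero(~region)[0]
        if len(free) == 0:
            continue
        s2, e2 = h.start + free[0], h.start + free[-1] + 1
        if covered[s2:e2].any():  # covered gap in the middle: true conflict
            continue
        if (s2 - h.start) > _BOUNDARY_TOL or (h.end - e2) > _BOUNDARY_TOL:
            continue
        if not MIN_MONOMER_LEN <= e2 - s2 <= MAX_MONOMER_LEN:
            continue
        segment = seq.bases[s2:e2]
        oriented = segment if h.strand == "+" else revcomp(segment)
        res = edlib.align(consensus.sequence, oriented, mode="NW", task="path")
        cols, matches = cigar_columns(res["cigar"])
        ident = matches / cols
        if ident < min_identity:
            continue
        covered[s2:e2] = True
        accepted.append(MonomerHit(h.seq_name, s2, e2, h.strand, oriented, ident))
    accepted.sort(key=lambda h: h.start)
    return accepted


def _close_small_gaps(hits: list[MonomerHit], seq: GenomeSequence) -> list[MonomerHit]:
    """Absorb sub-`_BOUNDARY_TOL` gaps between tandem hits into the left hit.

    A semi-global alignment occasionally ends a few bases short of the true
    monomer boundary; the unassigned bases would otherwise surface as
    spurious deletions in every downstream copy sequence.
    """
    out: list[MonomerHit] = []
    for i, h in enumerate(hits):
        nxt = hits[i + 1] if i + 1 < len(hits) else None
        if (
            nxt is not None
            and 0 < nxt.start - h.end < _BOUNDARY_TOL
            and h.strand == nxt.strand
            and nxt.start - h.start <= MAX_MONOMER_LEN
            and "N" not in seq.bases[h.end : nxt.start]
        ):
            segment = seq.bases[h.start : nxt.start]
            oriented = segment if h.strand == "+" else revcomp(segment)
            h = MonomerHit(h.seq_name, h.start, nxt.start, h.strand, oriented, h.identity)
        out.append(h)
    return out


def scan_monomers(
    seq: GenomeSequence,
    consensus: ConsensusMonomer,
    min_identity: float = 0.95,
) -> list[MonomerHit]:
    """Locate consensus monomers on both strands at >= `min_identity` identity.

    Returns a maximal non-overlapping hit set, sorted by start.
    """
    if seq.length < len(consensus):
        raise ValueError("sequence shorter than the consensus monomer")
    all_hits: dict[tuple[int, int, str], MonomerHit] = {}
    for strand in "+-":
        cons_or = consensus.sequence if strand == "+" else revcomp(consensus.sequence)
        starts = _candidate_starts(seq.bases, cons_or)
        all_hits.update(_hits_from_candidates(seq, starts, consensus, strand, min_identity))
    tiled = _greedy_tile(list(all_hits.values()), seq, consensus, min_identity)
    return _close_small_gaps(tiled, seq)


def exhaustive_scan(
    seq: GenomeSequence,
    consensus: ConsensusMonomer,
    min_identity: float = 0.95,
) -> list[MonomerHit]:
    """Brute-force variant of :func:`scan_monomers` trying every start position.

    Intended as an oracle on short sequences; identical retention and tiling
    rules, but candidate generation is exhaustive instead of seeded.
    """
    starts = range(0, seq.length - MIN_MONOMER_LEN + 1)
    all_hits: dict[tuple[int, int, str], MonomerHit] = {}
    for strand in "+-":
        all_hits.update(_hits_from_candidates(seq, starts, consensus, strand, min_identity))
    tiled = _greedy_tile(list(all_hits.values()), seq, consensus, min_identity)
    return _close_small_gaps(tiled, seq)


def filter_gap_overlaps(hits: Sequence[MonomerHit], seq: GenomeSequence) -> list[MonomerHit]:
    """Drop every hit whose interval contains at least one undefined base (N)."""
    return [h for h in hits if "N" not in seq.bases[h.start : h.end]]


def segment_arrays(hits: Sequence[MonomerHit], max_join_gap: int = 500) -> list[MonomerArray]:
    """Partition sorted hits into tandem arrays at gaps exceeding `max_join_gap` bp."""
    arrays: list[MonomerArray] = []
    current: list[MonomerHit] = []
    for h in hits:
        if current and (
            h.seq_name != current[-1].seq_name or h.start - current[-1].end > max_join_gap
        ):
            arrays.append(MonomerArray(current))
            current = []
        current.append(h)
    if current:
        arrays.append(MonomerArray(current))
    return arrays
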
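"""End-to-end orchestration: scan -> type -> MD/GRM -> HOR families -> outputs.

`analyze` is the library entry point and works on in-memory sequences;
`run_pipeline` wraps it with file I/O, writing BED/TSV/JSON outputs and a
run manifest.  Candidate HOR families are taken from MD line segments,
ranked by the segment's type-sequence autocorrelation mass at the period,
so that a full HOR unit claims its region before its intra-unit subfragment
and variant periods do; a claimed segment is expanded to the enclosing
monomer array so copies outside the strictly periodic core
(leading/trailing variants) are still segmented.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cascade import CascadeScheme, align_variant_schemes, classify_hor_type, layout_cascade
from .grm import MDPoint, PeriodHistogram, frequency_table, md_line_segments, md_points, period_histogram
from .hor import (
    DivergenceStats,
    HORFamily,
    classify_copies,
    define_canonical,
    divergence_stats,
    family_consensus,
    pick_anchor_and_segment,
)
from .monomer_types import TypeAssignment, cluster_types, reconcile_types_with_columns
from .monomers import (
    ConsensusMonomer,
    MonomerArray,
    MonomerHit,
    default_consensus,
    filter_gap_overlaps,
    load_consensus,
    scan_monomers,
    segment_arrays,
)
from .seqio import GenomeSequence, read_fasta, write_bed, write_json, write_tsv

__all__ = ["RunConfig", "FamilyResult", "AnalysisResult", "analyze", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised for unusable inputs or unwritable outputs."""


@dataclass
class RunConfig:
    fasta: str | Path
    consensus: Optional[str | Path] = None
    out_dir: Optional[str | Path] = None
    min_identity: float = 0.95
    type_threshold: float = 0.05
    max_period: int = 90
    max_join_gap: int = 500
    min_run: int = 20
    min_density: float = 0.5
    min_freq_report: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.type_threshold < 1:
            raise ValueError("type_threshold must be in (0, 1)")
        if self.max_period < 1 or self.min_run < 1:
            raise ValueError("max_period and min_run must be positive")


@dataclass
class FamilyResult:
    family: HORFamily
    region: tuple[int, int]  # enumeration interval analyzed
    consensus_seq: str
    stats: DivergenceStats
    scheme: CascadeScheme
    hor_type: str  # 'Willard' or 'Cascading'
    variant_table: pd.DataFrame

    @property
    def summary(self) -> dict:
        unit = self.family.canonical_type_seq
        return {
            "period": self.family.period,
            "n_copies": len(self.family.copies),
            "n_canonical": self.family.n_canonical,
            "n_variant": self.family.n_variant,
            "hor_type": "Willard's" if self.hor_type == "Willard" else "Cascading",
            "distinct_types": len(set(unit)),
            "repeated_types": len(unit) - len(set(unit)),
            "n_rows": self.scheme.n_rows,
            "row_counts": self.scheme.row_counts,
            "mean_divergence_pct": round(self.stats.mean_pct, 4),
            "cv_string": self.family.cv_string,
            "region": list(self.region),
        }


@dataclass
class AnalysisResult:
    sequences: list[GenomeSequence]
    hits: list[MonomerHit]
    arrays: list[MonomerArray]
    assignment: TypeAssignment
    points: list[MDPoint]
    histogram: PeriodHistogram
    families: list[FamilyResult]

    @property
    def monomer_table(self) -> pd.DataFrame:
        rows = []
        for enum, h in enumerate(self.hits, start=1):
            rows.append(
                {
                    "enumeration": enum,
                    "seq_name": h.seq_name,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "identity": round(h.identity, 5),
                    "type": self.assignment.types[enum],
                    "oriented_seq": h.oriented_seq,
                }
            )
        return pd.DataFrame(rows)


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    return max(inter, 0) / (a[1] - a[0] + 1)


def analyze(
    sequences: Sequence[GenomeSequence],
    consensus: ConsensusMonomer | None = None,
    *,
    min_identity: float = 0.95,
    type_threshold: float = 0.05,
    max_period: int = 90,
    max_join_gap: int = 500,
    min_run: int = 20,
    min_density: float = 0.5,
) -> AnalysisResult:
    """Run the full detection chain on in-memory sequences."""
    cons = consensus or default_consensus()
    all_hits: list[MonomerHit] = []
    for seq in sequences:
        if seq.length < len(cons):
            continue
        hits = scan_monomers(seq, cons, min_identity=min_identity)
        all_hits.extend(filter_gap_overlaps(hits, seq))
    arrays = segment_arrays(all_hits, max_join_gap=max_join_gap)
    oriented = [h.oriented_seq for h in all_hits]
    assignment = cluster_types(oriented, type_threshold=type_threshold)
    type_seq = assignment.type_seq()
    points = md_points(type_seq, max_period=max_period)
    histogram = period_histogram(points, max_period=max_period)

    # enumeration bounds per array, for segment expansion
    array_bounds: list[tuple[int, int]] = []
    e = 1
    for arr in arrays:
        array_bounds.append((e, e + len(arr) - 1))
        e += len(arr)

    # Candidate HOR periods: MD line segments ranked by the type-sequence
    # autocorrelation mass of the segment, i.e. how many positions satisfy
    # type[i] == type[i+p].  At the full unit period this holds at every
    # position of every tandem copy pair, so the full n-mer dominates both
    # intra-unit subfragment periods (the period-2 doublet inside an 18mer
    # matches at only half the positions) and variant-offset periods
    # (period n±1 across an indel variant matches only near the variant).
    ts_arr = np.asarray(type_seq)
    candidates: list[tuple[int, int, tuple[int, int]]] = []
    for p in range(2, max_period + 1):
        if histogram[p] < min_run:
            continue
        for seg in md_line_segments(points, p, min_run=min_run, min_density=min_density):
            a, b = seg[0] - 1, min(seg[1], len(ts_arr) - p)
            score = int(np.count_nonzero(ts_arr[a:b] == ts_arr[a + p : b + p])) if b > a else 0
            candidates.append((score, p, seg))
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))

    families: list[FamilyResult] = []
    claimed: list[tuple[int, int]] = []
    for _score, p, seg in candidates:
        if any(_overlap_frac(seg, c) > 0.5 for c in claimed):
            continue
        region = seg
        for bounds in array_bounds:
            if bounds[0] <= seg[0] and seg[1] <= bounds[1]:
                untouched = all(min(bounds[1], c[1]) < max(bounds[0], c[0]) for c in claimed)
                if untouched:
                    region = bounds
                break
        copies = pick_anchor_and_segment(type_seq, region, p, monomer_seqs=oriented)
        if len(copies) < 2:
            continue
        canonical = define_canonical(copies, p)
        family = classify_copies(copies, canonical)
        assignment = reconcile_types_with_columns(assignment, family.copies, type_threshold)
        type_seq = assignment.type_seq()
        # rebuild copies under the reconciled assignment and re-classify once
        for c in family.copies:
            c.type_seq = [type_seq[c.start_enum - 1 + k] for k in range(c.m)]
        canonical = define_canonical(family.copies, p)
        family = classify_copies(family.copies, canonical)
        canonical_copies = [c for c in family.copies if c.label == "C"]
        if not canonical_copies:
            continue
        cons_seq = family_consensus(canonical_copies, assignment.centroids)
        stats = divergence_stats(canonical_copies, cons_seq)
        scheme = layout_cascade(canonical)
        variant_schemes = []
        variant_labels = [f"C{family.period}"]
        seen: set[tuple[int, ...]] = set()
        for c in family.copies:
            if c.label != "C" and tuple(c.type_seq) not in seen:
                seen.add(tuple(c.type_seq))
                variant_schemes.append(layout_cascade(c.type_seq, column_order=scheme.columns))
                variant_labels.append(c.label)
        table = align_variant_schemes(scheme, variant_schemes, labels=variant_labels)
        families.append(
            FamilyResult(
                family=family,
                region=region,
                consensus_seq=cons_seq,
                stats=stats,
                scheme=scheme,
                hor_type=classify_hor_type(scheme),
                variant_table=table,
            )
        )
        claimed.append(region)
    families.sort(key=lambda f: f.region[0])
    return AnalysisResult(
        sequences=list(sequences),
        hits=all_hits,
        arrays=arrays,
        assignment=assignment,
        points=points,
        histogram=histogram,
        families=families,
    )


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run `analyze` on a FASTA file and write all outputs to the run directory."""
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise PipelineError(f"input FASTA not found: {fasta}")
    try:
        seqs = read_fasta(fasta)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc
    cons = load_consensus(config.consensus) if config.consensus else default_consensus()
    out_dir = Path(config.out_dir or "horscan_run")
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create output directory {out_dir}: {exc}") from exc

    result = analyze(
        seqs,
        cons,
        min_identity=config.min_identity,
        type_threshold=config.type_threshold,
        max_period=config.max_period,
        max_join_gap=config.max_join_gap,
        min_run=config.min_run,
        min_density=config.min_density,
    )

    mono = result.monomer_table
    if len(mono):
        write_bed(
            [
                (r.seq_name, r.start, r.end, f"mon_t{r.type}", int(round(r.identity * 1000)), r.strand)
                for r in mono.itertuples()
            ],
            out_dir / "monomers.bed",
        )
    else:
        (out_dir / "monomers.bed").write_text("")
    write_tsv(mono, out_dir / "monomers.tsv")
    write_tsv(
        pd.DataFrame([(p.enumeration, p.period) for p in result.points], columns=["enumeration", "period"]),
        out_dir / "md_points.tsv",
    )
    write_tsv(frequency_table(result.histogram, config.min_freq_report), out_dir / "period_frequencies.tsv")

    summaries = []
    for i, fam in enumerate(result.families, start=1):
        fdir = out_dir / f"family_{i}_{fam.family.period}mer"
        fdir.mkdir(exist_ok=True)
        rows = []
        for k, c in enumerate(fam.family.copies):
            div = (
                100.0 * _copy_divergence(c, fam.consensus_seq)
                if c.label == "C"
                else float("nan")
            )
            rows.append(
                {"copy": k, "start_enum": c.start_enum, "label": c.label, "m": c.m,
                 "divergence_to_consensus_pct": round(div, 4) if div == div else ""}
            )
        write_tsv(pd.DataFrame(rows), fdir / "copies.tsv")
        (fdir / "cv_string.txt").write_text(fam.family.cv_string + "\n")
        (fdir / "consensus.fasta").write_text(
            f">family_{i}_{fam.family.period}mer_consensus\n{fam.consensus_seq}\n"
        )
        scheme_rows = [
            {"row": r, "column": c, "offset": off, "type": t}
            for r, c, off, t in sorted(fam.scheme.placements, key=lambda p: p[2])
        ]
        write_tsv(pd.DataFrame(scheme_rows), fdir / "cascade_scheme.tsv")
        fam.variant_table.to_csv(fdir / "variant_table.tsv", sep="\t")
        summaries.append(fam.summary)
    write_json({"families": summaries}, out_dir / "summary.json")

    manifest = {
        "version": __version__,
        "config": {
            "fasta": str(fasta),
            "consensus": str(config.consensus) if config.consensus else "builtin",
            "min_identity": config.min_identity,
            "type_threshold": config.type_threshold,
            "max_period": config.max_period,
            "max_join_gap": config.max_join_gap,
            "min_run": config.min_run,
            "min_density": config.min_density,
            "seed": config.seed,
        },
        "input_md5": _md5(fasta),
        "n_monomers": len(result.hits),
        "n_arrays": len(result.arrays),
        "n_types": result.assignment.n_types,
        "n_families": len(result.families),
    }
    write_json(manifest, out_dir / "manifest.json")
    return out_dir


def _copy_divergence(copy, consensus_seq: str) -> float:
    from .monomer_types import pairwise_divergence

    return pairwise_divergence(copy.nt_seq, consensus_seq)
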
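"""Reading, slicing and writing pairwise IBD segment calls.

Input is the tab-delimited pairwise-segment dialect used by Beagle's
Refined IBD: one row per call with columns

    sample1  hap1  sample2  hap2  chromosome  start_bp  end_bp  LOD

Coordinates are 1-based inclusive.  Internally the package works with
half-open intervals (``end + 1``), converting back on output.  The writer
appends two columns — the updated probability and an inferred flag — and
its files round-trip through :func:`read_segments`.

The genome is cut at *breakpoints*: the unique positions where any
segment begins or ends.  Between consecutive breakpoints the set of
covering segments (hence the IBD graph) is constant, so each such
interval is analysed once.  Within an interval, haplotypes incident to a
covering segment become nodes, called pairs get calibrated probabilities,
and — within each connected component of called edges — uncalled pairs
get the epsilon prior.  Disjoint components are independent inference
problems.

After per-region conditioning, same-pair results are merged back into
segments: adjacent or overlapping pieces whose probabilities pass a
threshold fuse into one segment carrying the maximum probability, and
uncalled pairs whose conditional probability passes the threshold become
newly inferred segments spanning the intersection of their component's
member-segment intervals (the graph carries no sequence information, so
the intersection is the only interval the evidence localises).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .calibration import CalibrationParams, lod_to_probability
from .graph import HaplotypeId, ProbabilisticIBDGraph, edge_key

__all__ = [
    "SegmentFormatError",
    "IBDSegment",
    "GeneticMap",
    "AnalysisRegion",
    "read_segments",
    "write_segments",
    "filter_segments",
    "segment_length_cm",
    "breakpoints",
    "build_region_graphs",
    "merge_segments",
    "merge_across_regions",
    "infer_new_segments",
]

logger = logging.getLogger(__name__)

#: fallback genetic-map scale when no map is supplied (1 cM per Mb,
#: i.e. a uniform 1e-8 per-bp recombination rate)
DEFAULT_CM_PER_MB = 1.0


class SegmentFormatError(ValueError):
    """Raised for malformed segment files; carries the offending line number."""


@dataclass(frozen=True)
class IBDSegment:
    """One pairwise IBD call (or truth segment).

    Haplotypes are stored in canonical order (``hap_a < hap_b``);
    coordinates are 1-based inclusive.  ``lod`` and ``prob`` are both
    optional so the type can carry raw calls, calibrated calls and truth
    segments alike.
    """

    hap_a: HaplotypeId
    hap_b: HaplotypeId
    chrom: str
    start_bp: int
    end_bp: int
    lod: float | None = None
    prob: float | None = None
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.hap_b < self.hap_a:
            a, b = self.hap_a, self.hap_b
            object.__setattr__(self, "hap_a", b)
            object.__setattr__(self, "hap_b", a)
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"segment start {self.start_bp} after end {self.end_bp}"
            )
        if self.hap_a == self.hap_b:
            raise ValueError(f"segment joins haplotype {self.hap_a} to itself")

    @property
    def pair(self) -> tuple:
        return (self.hap_a, self.hap_b)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def length_cm(self, gmap: "GeneticMap | None" = None) -> float:
        return segment_length_cm(self, gmap)


def _make_segment(hap_a, hap_b, chrom, start_bp, end_bp, lod=None, prob=None, inferred=False) -> IBDSegment:
    if hap_b < hap_a:
        hap_a, hap_b = hap_b, hap_a
    return IBDSegment(hap_a, hap_b, str(chrom), int(start_bp), int(end_bp), lod, prob, inferred)


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome piecewise-linear bp-to-cM interpolation tables.

    Positions must be strictly increasing in bp with non-decreasing cM.
    Queries outside the mapped range are clamped to the boundary values;
    chromosomes absent from the map fall back to a constant rate.
    """

    table: Mapping[str, tuple]
    default_cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.table.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
                raise ValueError(f"map for chromosome {chrom} needs >= 2 (bp, cM) points")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions must strictly increase on chromosome {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions must be non-decreasing on chromosome {chrom}")

    @classmethod
    def read(cls, path, default_cm_per_mb: float = DEFAULT_CM_PER_MB) -> "GeneticMap":
        """Read a PLINK ``.map`` (chrom, id, cM, bp) or a three-column
        (chrom, bp, cM) whitespace-delimited table."""
        per_chrom: dict[str, list[tuple[float, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                try:
                    if len(parts) == 4:  # PLINK: chrom id cM bp
                        chrom, _, cm, bp = parts
                    elif len(parts) == 3:  # chrom bp cM
                        chrom, bp, cm = parts
                    else:
                        raise ValueError(f"expected 3 or 4 columns, got {len(parts)}")
                    per_chrom.setdefault(chrom, []).append((float(bp), float(cm)))
                except ValueError as exc:
                    raise SegmentFormatError(f"{path}, line {lineno}: {exc}") from None
        table = {}
        for chrom, pts in per_chrom.items():
            pts.sort()
            bp = np.asarray([p[0] for p in pts])
            cm = np.asarray([p[1] for p in pts])
            table[chrom] = (bp, cm)
        return cls(table, default_cm_per_mb)

    def cm_at(self, chrom: str, bp: int) -> float:
        entry = self.table.get(str(chrom))
        if entry is None:
            return bp * self.default_cm_per_mb / 1e6
        xs, ys = entry
        return float(np.interp(float(bp), xs, ys))

    def length_cm(self, chrom: str, start_bp: int, end_bp: int) -> float:
        return self.cm_at(chrom, end_bp) - self.cm_at(chrom, start_bp)


def segment_length_cm(seg: IBDSegment, gmap: GeneticMap | None = None) -> float:
    """Centimorgan length of a segment (constant 1 cM/Mb without a map)."""
    if gmap is None:
        return seg.length_bp * DEFAULT_CM_PER_MB / 1e6
    return gmap.length_cm(seg.chrom, seg.start_bp, seg.end_bp)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_HEADER = "#sample1\thap1\tsample2\thap2\tchrom\tstart_bp\tend_bp\tlod\tprob\tinferred"


def _parse_optional_float(text: str) -> float | None:
    if text in ("", "NA", "na", "."):
        return None
    return float(text)


def read_segments(path, errors: str = "raise") -> list[IBDSegment]:
    """Read tab-delimited pairwise IBD calls.

    Accepts the plain 8-column caller dialect as well as this package's
    9/10-column output (probability and inferred flag).  With
    ``errors="skip"`` malformed rows are logged (with their line numbers)
    and dropped instead of raising.
    """
    if errors not in ("raise", "skip"):
        raise ValueError("errors must be 'raise' or 'skip'")
    segs: list[IBDSegment] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) not in (8, 9, 10):
                msg = f"{path}, line {lineno}: expected 8-10 tab-delimited columns, got {len(parts)}"
                if errors == "raise":
                    raise SegmentFormatError(msg)
                logger.warning(msg)
                n_bad += 1
                continue
            try:
                hap_a = HaplotypeId(parts[0], int(parts[1]))
                hap_b = HaplotypeId(parts[2], int(parts[3]))
                chrom = parts[4]
                start_bp = int(parts[5])
                end_bp = int(parts[6])
                lod = _parse_optional_float(parts[7])
                prob = _parse_optional_float(parts[8]) if len(parts) > 8 else None
                inferred = parts[9] == "1" if len(parts) > 9 else False
                segs.append(_make_segment(hap_a, hap_b, chrom, start_bp, end_bp, lod, prob, inferred))
            except (ValueError, IndexError) as exc:
                msg = f"{path}, line {lineno}: {exc}"
                if errors == "raise":
                    raise SegmentFormatError(msg) from None
                logger.warning(msg)
                n_bad += 1
    if not segs:
        logger.warning("no segments read from %s (%d malformed rows)", path, n_bad)
    return segs


def write_segments(segs: Iterable[IBDSegment], path) -> None:
    """Write segments in the input dialect plus probability and inferred
    columns; the output round-trips through :func:`read_segments`."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for seg in segs:
            lod = "NA" if seg.lod is None else f"{seg.lod:.6g}"
            prob = "NA" if seg.prob is None else f"{seg.prob:.6f}"
            fh.write(
                f"{seg.hap_a.sample}\t{seg.hap_a.hap_index}\t"
                f"{seg.hap_b.sample}\t{seg.hap_b.hap_index}\t"
                f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t"
                f"{lod}\t{prob}\t{int(seg.inferred)}\n"
            )


def filter_segments(
    segs: Iterable[IBDSegment],
    min_lod: float = 0.1,
    min_cm: float = 0.1,
    gmap: GeneticMap | None = None,
) -> list[IBDSegment]:
    """Keep calls with ``lod >= min_lod`` and length ``>= min_cm``.

    Segments without a LOD (truth or probability-only records) pass the
    LOD filter untouched.
    """
    out = []
    for seg in segs:
        if seg.lod is not None and seg.lod < min_lod:
            continue
        if segment_length_cm(seg, gmap) < min_cm:
            continue
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisRegion:
    """One constant-graph stretch between consecutive breakpoints.

    ``start_bp``/``end_bp`` delimit a half-open interval ``[start, end)``.
    ``components`` are the probabilistic graphs of the connected
    components of called edges, each an independent inference problem;
    ``called_pairs`` records which pairs carry a real call (everything
    else inside a component sits at the epsilon prior).
    """

    chrom: str
    start_bp: int
    end_bp: int
    segments: tuple
    components: tuple
    called_pairs: frozenset

    @property
    def graph(self) -> ProbabilisticIBDGraph:
        """All components merged into one graph (epsilon across components)."""
        nodes: list = []
        probs: dict = {}
        eps = self.components[0].epsilon if self.components else None
        for comp in self.components:
            nodes.extend(comp.nodes)
            probs.update(dict(comp.edge_items()))
        return ProbabilisticIBDGraph(
            nodes, probs, region=(self.chrom, self.start_bp, self.end_bp),
            epsilon=eps if eps is not None else 0.0046,
        )


def breakpoints(segs: Iterable[IBDSegment]) -> dict[str, np.ndarray]:
    """Unique segment starts and ``end + 1`` positions per chromosome.

    Consecutive positions delimit the half-open analysis intervals over
    which the IBD graph is constant.
    """
    per_chrom: dict[str, set[int]] = {}
    for seg in segs:
        pts = per_chrom.setdefault(seg.chrom, set())
        pts.add(seg.start_bp)
        pts.add(seg.end_bp + 1)
    return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in sorted(per_chrom.items())}


def build_region_graphs(
    segs: Sequence[IBDSegment],
    calib: CalibrationParams | None = None,
    empirical=None,
) -> list[AnalysisRegion]:
    """Cut the genome at breakpoints and build per-region graphs.

    For every interval with at least one covering segment: called pairs
    get ``lod_to_probability`` values (a segment already carrying ``prob``
    keeps it; multiple covering calls for one pair keep the maximum), and
    each connected component becomes a :class:`ProbabilisticIBDGraph`
    whose uncalled within-component pairs sit at the epsilon prior.
    """
    calib = calib or CalibrationParams()
    regions: list[AnalysisRegion] = []
    by_chrom: dict[str, list[IBDSegment]] = {}
    for seg in segs:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in sorted(by_chrom):
        chrom_segs = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp))
        pts = breakpoints(chrom_segs)[chrom]
        for a, b in zip(pts[:-1], pts[1:]):
            covering = [s for s in chrom_segs if s.start_bp <= a and s.end_bp + 1 >= b]
            if not covering:
                continue
            pair_prob: dict[tuple, float] = {}
            for seg in covering:
                p = seg.prob if seg.prob is not None else lod_to_probability(seg.lod, calib, empirical)
                key = edge_key(seg.hap_a, seg.hap_b)
                pair_prob[key] = max(p, pair_prob.get(key, 0.0))
            g = nx.Graph()
            g.add_edges_from(pair_prob.keys())
            comps = []
            for comp_nodes in nx.connected_components(g):
                nodes = sorted(comp_nodes)
                probs = {
                    k: v for k, v in pair_prob.items() if k[0] in comp_nodes
                }
                comps.append(
                    ProbabilisticIBDGraph(
                        nodes,
                        probs,
                        region=(chrom, int(a), int(b)),
                        epsilon=calib.epsilon,
                    )
                )
            comps.sort(key=lambda c: c.nodes[0])
            regions.append(
                AnalysisRegion(
                    chrom=chrom,
                    start_bp=int(a),
                    end_bp=int(b),
                    segments=tuple(covering),
                    components=tuple(comps),
                    called_pairs=frozenset(pair_prob),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# merging and inference of new segments
# ---------------------------------------------------------------------------


def merge_segments(pieces: Iterable[IBDSegment], threshold: float = 0.99) -> list[IBDSegment]:
    """Fuse adjacent/overlapping same-pair pieces that pass ``threshold``.

    Pieces below the threshold are emitted unmerged; merged segments carry
    the maximum probability of their parts and are flagged inferred if any
    part was.  Pairs and chromosomes are never merged across.
    """
    by_key: dict[tuple, list[IBDSegment]] = {}
    for seg in pieces:
        by_key.setdefault((seg.chrom, seg.pair), []).append(seg)
    out: list[IBDSegment] = []
    for key in sorted(by_key, key=lambda k: (k[0], str(k[1]))):
        group = sorted(by_key[key], key=lambda s: (s.start_bp, s.end_bp))
        run: IBDSegment | None = None
        for seg in group:
            passes = seg.prob is not None and seg.prob >= threshold
            if not passes:
                out.append(seg)
                continue
            if run is not None and seg.start_bp <= run.end_bp + 1:
                run = replace(
                    run,
                    end_bp=max(run.end_bp, seg.end_bp),
                    prob=max(run.prob, seg.prob),
                    lod=max(
                        (x for x in (run.lod, seg.lod) if x is not None),
                        default=None,
                    ),
                    inferred=run.inferred and seg.inferred,
                )
            else:
                if run is not None:
                    out.append(run)
                run = seg
        if run is not None:
            out.append(run)
    out.sort(key=lambda s: (s.chrom, s.start_bp, s.end_bp, str(s.hap_a), str(s.hap_b)))
    return out


def _region_pieces(region: AnalysisRegion, p_hat: Mapping[tuple, float]) -> list[IBDSegment]:
    pieces = []
    for pair in region.called_pairs:
        p = p_hat.get(pair)
        if p is None:
            continue
        pieces.append(
            _make_segment(
                pair[0], pair[1], region.chrom,
                region.start_bp, region.end_bp - 1,
                prob=float(p),
            )
        )
    return pieces


def merge_across_regions(
    results: Iterable[tuple[AnalysisRegion, Mapping[tuple, float]]],
    threshold: float = 0.99,
) -> list[IBDSegment]:
    """Merge per-region conditional probabilities back into segments.

    ``results`` pairs each analysed region with its conditional edge
    probabilities.  Called pairs become per-region pieces (1-based
    inclusive coordinates) which :func:`merge_segments` fuses wherever
    adjacent same-pair pieces pass the threshold, keeping the maximum
    probability; a merged probability therefore never decreases.
    """
    pieces: list[IBDSegment] = []
    for region, p_hat in results:
        pieces.extend(_region_pieces(region, p_hat))
    return merge_segments(pieces, threshold)


def infer_new_segments(
    region: AnalysisRegion,
    p_hat: Mapping[tuple, float],
    threshold: float = 0.99,
) -> list[IBDSegment]:
    """Segments for uncalled pairs whose conditional probability passes
    ``threshold``.

    The emitted interval is the intersection of all member-segment
    intervals of the pair's connected component — the graph carries no
    sequence evidence, so IBD can only be localised to where every
    supporting call overlaps.  Every member segment covers the analysis
    interval, so the intersection is never empty.
    """
    out: list[IBDSegment] = []
    for comp in region.components:
        comp_nodes = set(comp.nodes)
        members = [
            s for s in region.segments
            if s.hap_a in comp_nodes and s.hap_b in comp_nodes
        ]
        if not members:
            continue
        istart = max(s.start_bp for s in members)
        iend = min(s.end_bp for s in members)
        assert istart <= iend, "member segments must share the analysis interval"
        for pair in comp.pairs():
            if pair in region.called_pairs:
                continue
            p = p_hat.get(pair)
            if p is None or p < threshold:
                continue
            out.append(
                _make_segment(
                    pair[0], pair[1], region.chrom, istart, iend,
                    prob=float(p), inferred=True,
                )
            )
    return out
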
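"""Kimura 2-parameter divergence, 1%-binned landscapes, and peak calling.

The K2P distance corrects observed substitution proportions for multiple hits,
treating transitions (A<->G, C<->T) and transversions at separate rates:

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over compared sites.
Landscapes bin monomer-to-consensus distances at 1% and peaks are runs of bins
standing 50% above their flanking bins; peak positions diagnose recent
amplification (low divergence) versus aged, non-homogenized variants (high
divergence).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from satkit.alignment import global_align

logger = logging.getLogger("satkit")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class DivergenceRecord:
    P: float
    Q: float
    d: float
    compared_sites: int
    monomer_id: str | None = None

    @property
    def saturated(self) -> bool:
        return math.isinf(self.d)


def k2p_from_proportions(P: float, Q: float) -> float:
    """Closed-form K2P distance; +inf when the correction saturates."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(aligned_a: str, aligned_b: str, monomer_id: str | None = None) -> DivergenceRecord:
    """K2P distance over an aligned, equal-length pair of sequences.

    Gap columns and columns containing N are excluded from the compared sites
    (transition/transversion status is undefined for them).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("k2p_distance requires equal-length aligned sequences")
    transitions = transversions = sites = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    P, Q = transitions / sites, transversions / sites
    d = k2p_from_proportions(P, Q)
    return DivergenceRecord(P=P, Q=Q, d=d, compared_sites=sites, monomer_id=monomer_id)


def k2p_between(seq: str, consensus: str, monomer_id: str | None = None) -> DivergenceRecord:
    """Align a monomer to the consensus (package-wide scoring), then K2P."""
    ga, gb = global_align(seq, consensus)
    return k2p_distance(ga, gb, monomer_id=monomer_id)


def hit_divergence_records(hits, genome, family) -> list[DivergenceRecord]:
    """K2P records for annotated monomer hits against their consensus.

    Each hit is read 5'->3' on its own strand and compared against the
    consensus rotated to the hit's phase — the comparison the landscape is
    built from.
    """
    from satkit.records import revcomp, rotate  # local import to avoid a cycle

    if not isinstance(genome, list):
        genome = [genome]
    seqs = {g.seq_id: g.sequence for g in genome}
    records = []
    for h in hits:
        seg = seqs[h.seq_id][h.start : h.end]
        if h.strand == "-":
            seg = revcomp(seg)
        ref = rotate(family.consensus, h.rotation)
        records.append(k2p_between(seg, ref, monomer_id=f"{h.seq_id}:{h.start}"))
    return records


# -- vectorized path for simulation-scale batches ---------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

_IS_PURINE = np.array([True, False, True, False])  # A C G T


def encode(seq: str) -> np.ndarray:
    """Encode ACGT(N) to uint8 codes 0..3 (others -> 255)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] if c < 4 else "N" for c in codes)


def k2p_batch(monomers: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """K2P distances for a (n, L) code matrix against a length-L consensus.

    Positions where either side is not a plain base are excluded per row.
    Saturated rows come back as +inf.
    """
    valid = (monomers < 4) & (consensus[None, :] < 4)
    sites = valid.sum(axis=1).astype(float)
    diff = (monomers != consensus[None, :]) & valid
    pur_m = _IS_PURINE[np.clip(monomers, 0, 3)]
    pur_c = _IS_PURINE[np.clip(consensus, 0, 3)][None, :]
    ts = (diff & (pur_m == pur_c)).sum(axis=1)
    tv = (diff & (pur_m != pur_c)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P, Q = ts / sites, tv / sites
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(np.maximum(w1, 1e-300) * np.sqrt(np.maximum(w2, 1e-300))), np.inf)
    return d


# -- landscapes -------------------------------------------------------------

@dataclass
class DivergenceLandscape:
    family_id: str
    bin_width: float
    values: np.ndarray  # abundance per bin (monomer count by default)
    bp_values: np.ndarray | None = None
    n_saturated: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_range(self, k: int) -> tuple[float, float]:
        return k * self.bin_width, (k + 1) * self.bin_width


def build_landscape(
    records,
    bin_width: float = 0.01,
    family_id: str = "",
    n_bins: int | None = None,
    lengths=None,
) -> DivergenceLandscape:
    """Bin finite distances into [k*w, (k+1)*w) bins.

    ``records`` may be DivergenceRecord objects or plain floats. Saturated
    (infinite) distances are excluded with a logged count. If ``lengths`` is
    given, a bp-weighted abundance track is emitted alongside the count track.
    """
    ds = np.array([r.d if isinstance(r, DivergenceRecord) else float(r) for r in records])
    lens = None if lengths is None else np.asarray(lengths, dtype=float)
    finite = np.isfinite(ds)
    n_sat = int((~finite).sum())
    if n_sat:
        logger.info("landscape %s: %d saturated distances excluded", family_id, n_sat)
    ds_f = ds[finite]
    if n_bins is None:
        top = float(ds_f.max()) if len(ds_f) else 0.0
        n_bins = max(1, int(top / bin_width) + 1)
    values = np.zeros(n_bins)
    bp_values = np.zeros(n_bins) if lens is not None else None
    idx = np.minimum((ds_f / bin_width).astype(int), n_bins - 1)
    np.add.at(values, idx, 1)
    if lens is not None:
        np.add.at(bp_values, idx, lens[finite])
    return DivergenceLandscape(family_id, bin_width, values, bp_values, n_sat)


# -- peak calling -----------------------------------------------------------

@dataclass
class Peak:
    start_bin: int
    end_bin: int  # inclusive
    apex_bin: int
    apex_value: float
    centroid_bin: float = 0.0  # abundance-weighted mean bin over the run

    @property
    def bins(self) -> range:
        return range(self.start_bin, self.end_bin + 1)


def _qualifying_runs_adjacent(v: np.ndarray, factor: float):
    """Strict adjacent-bin reading: runs whose every bin is >= factor x the
    bins immediately outside the run.

    A qualifying run contains no zero bins (an empty class cannot stand above
    anything) and is delimited by at least one positive neighboring bin — a
    run whose both flanks are empty (or off the landscape) is the whole
    distribution, or an isolated island, not a local maximum within it.
    The *innermost* qualifying runs are the peaks (a run containing another
    qualifying run is a shoulder around a sharper peak).
    """
    K = len(v)
    runs = []
    for i in range(K):
        left = v[i - 1] if i > 0 else 0.0
        run_min = math.inf
        for j in range(i, K):
            if v[j] == 0:
                break
            run_min = min(run_min, v[j])
            right = v[j + 1] if j + 1 < K else 0.0
            if (
                (left > 0 or right > 0)
                and run_min >= factor * left
                and run_min >= factor * right
            ):
                runs.append((i, j))
    return [
        (i, j)
        for (i, j) in runs
        if not any((i <= i2 and j2 <= j) and (i2, j2) != (i, j) for (i2, j2) in runs)
    ]


def _segments(v: np.ndarray):
    """Maximal runs of positive bins."""
    segs = []
    i = 0
    while i < len(v):
        if v[i] > 0:
            j = i
            while j + 1 < len(v) and v[j + 1] > 0:
                j += 1
            segs.append((i, j))
            i = j + 1
        else:
            i += 1
    return segs


def _runs_prominence(v: np.ndarray, factor: float):
    """Default reading: local maxima standing ``factor`` above their flanking
    valleys.

    Within each positive-support segment, local-maximum plateaus are merged
    across any valley shallower than ``factor`` (the smaller apex is absorbed,
    left kept on ties). A surviving apex is a peak if, on each side, it is
    either open (landscape edge or empty bin: the condition is one-sided) or
    stands >= factor x the minimum bin between it and the neighboring apex or
    segment edge — and at least one side offers a positive comparison bin.
    The reported run is the maximal run around the apex whose every bin is
    >= factor x the largest positive comparison value.
    """
    runs = []
    for a, b in _segments(v):
        # local-maximum plateaus
        cands = []
        i = a
        while i <= b:
            j = i
            while j + 1 <= b and v[j + 1] == v[i]:
                j += 1
            left_ok = i == a or v[i - 1] < v[i]
            right_ok = j == b or v[j + 1] < v[i]
            if left_ok and right_ok:
                cands.append((i, j))
            i = j + 1
        # merge across shallow valleys (weakest-first would also do; a
        # left-to-right sweep repeated to fixpoint is deterministic)
        changed = True
        while changed and len(cands) > 1:
            changed = False
            for idx in range(len(cands) - 1):
                (pi, pj), (qi, qj) = cands[idx], cands[idx + 1]
                valley = v[pj + 1 : qi].min()
                if min(v[pi], v[qi]) < factor * valley:
                    drop = idx + 1 if v[pi] >= v[qi] else idx
                    cands.pop(drop)
                    changed = True
                    break
        for idx, (pi, pj) in enumerate(cands):
            apex = v[pi]
            refs = []
            ok = True
            # left side
            lo = cands[idx - 1][1] + 1 if idx > 0 else a
            if pi > lo:
                ref = v[lo:pi].min()
                refs.append(ref)
                ok &= apex >= factor * ref
            # else: apex at segment start; outside is a zero bin or the
            # landscape edge -> one-sided condition
            hi = cands[idx + 1][0] if idx + 1 < len(cands) else b + 1
            if pj + 1 < hi:
                ref = v[pj + 1 : hi].min()
                refs.append(ref)
                ok &= apex >= factor * ref
            if not ok or not refs:
                continue
            bound = factor * max(refs)
            i = pi
            while i - 1 >= a and v[i - 1] >= bound:
                i -= 1
            j = pj
            while j + 1 <= b and v[j + 1] >= bound:
                j += 1
            runs.append((i, j))
    return runs


def call_peaks(
    landscape,
    peak_factor: float = 1.5,
    rule: str = "prominence",
    min_peak_fraction: float = 0.02,
) -> list[Peak]:
    """Call peaks: bins (or series of neighboring bins) standing
    ``peak_factor`` above the bins flanking them.

    The default ``prominence`` rule compares each local maximum against the
    valleys separating it from its neighbors (see :func:`_runs_prominence`);
    the stricter ``adjacent`` rule demands every bin of a run to stand above
    the bins immediately outside it. ``min_peak_fraction`` drops peaks whose
    run holds less than that fraction of total abundance — sampling noise in
    sparse regions otherwise forms spurious few-monomer "peaks" (see the
    methods note). Peaks come back disjoint, left to right.
    """
    v = landscape.values if isinstance(landscape, DivergenceLandscape) else np.asarray(landscape, dtype=float)
    if rule == "prominence":
        runs = _runs_prominence(v, peak_factor)
    elif rule == "adjacent":
        runs = _qualifying_runs_adjacent(v, peak_factor)
    else:
        raise ValueError(f"unknown peak rule {rule!r}")
    floor = min_peak_fraction * float(v.sum())
    peaks = []
    for i, j in sorted(runs):
        seg = v[i : j + 1]
        if seg.sum() < floor:
            continue
        apex = i + int(np.argmax(seg))
        centroid = float((np.arange(i, j + 1) * seg).sum() / seg.sum())
        peaks.append(Peak(i, j, apex, float(v[apex]), centroid))
    return peaks


def classify_landscape(peaks: list[Peak]) -> str:
    """Shape label from called peaks.

    unimodal_low: single peak with apex below the 10% bin; unimodal_shifted:
    single peak at or beyond it; bimodal: exactly two; multimodal: three or
    more; flat: none.
    """
    if not peaks:
        logger.info("landscape has no peaks; labelling flat")
        return "flat"
    if len(peaks) == 1:
        return "unimodal_low" if peaks[0].apex_bin < 10 else "unimodal_shifted"
    return "bimodal" if len(peaks) == 2 else "multimodal"
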
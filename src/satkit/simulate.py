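"""Synthetic satellitomes with machine-readable truth.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_genome` — multi-chromosome genome with planted satDNA
  arrays (interspersed / terminal-block / single-block / chromosome-restricted
  placement), per-monomer divergence drawn from a mixture so landscapes come
  out uni- or multimodal, optional conserved cassettes flanking every array.
* :func:`simulate_reads` — RNA-seq-like reads drawn from each family's
  head-to-tail dimer under a stage x sex expression design, plus random
  background reads.
* :func:`simulate_presence` — a BLAST-style taxon x family coverage table
  planted so that the MRCA of the qualifying taxa is a chosen node of a dated
  tree.

The substitution process matches the K2P estimator: per site, a transition
with probability P and each transversion with probability Q/2, with P/Q equal
to the requested transition:transversion count ratio (kappa) and (P, Q)
solved from the K2P closed form so the expected measured distance equals the
requested divergence. Substitution-only by default; divergence math and the
45% annotation ceiling are defined over substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from satkit.divergence import decode, encode, k2p_batch, k2p_from_proportions
from satkit.records import GenomeSequence, SatFamily, revcomp, rotate
from satkit.trees import DatedTree

PLACEMENT_MODES = ("interspersed", "terminal_blocks", "single_block", "restricted_chromosome")

STAGES = (
    "egg",
    "early_larva",
    "mid_larva",
    "late_larva",
    "early_pupa",
    "late_pupa",
    "early_adult",
    "late_adult",
)


@dataclass
class FamilySimSpec:
    family: SatFamily
    placement_mode: str = "interspersed"
    n_arrays: int = 10
    array_length_range: tuple[int, int] = (2, 20)
    divergence_mixture: tuple[tuple[float, float, float], ...] = ((1.0, 0.05, 0.01),)
    kappa: float = 2.0
    flank_cassette: str | None = None

    def __post_init__(self) -> None:
        if self.placement_mode not in PLACEMENT_MODES:
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")
        weights = [w for w, _m, _s in self.divergence_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("divergence mixture weights must sum to 1")
        for _w, mean, _sd in self.divergence_mixture:
            if not 0 <= mean <= 0.45:
                raise ValueError("mixture mean divergences must lie in [0, 0.45]")
        if self.array_length_range[0] < 1 or self.array_length_range[0] > self.array_length_range[1]:
            raise ValueError("array_length_range must satisfy 1 <= min <= max")
        if self.placement_mode == "single_block" and self.n_arrays != 1:
            raise ValueError("single_block placement requires n_arrays == 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class TruthTable:
    """Ground truth for planted features; one row per planted feature."""

    monomers: pd.DataFrame | None = None  # chrom,start,end,family,strand,rotation,divergence,target_divergence,array_id
    arrays: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None  # library,family,count
    presence: pd.DataFrame | None = None  # taxon,family,query_coverage,present
    ages: pd.DataFrame | None = None  # family,planted_age

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("monomers", "arrays", "expression", "presence", "ages"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# substitution process
# ---------------------------------------------------------------------------

def _k2p_jensen_bias(P: float, Q: float, n_sites: int) -> float:
    """Second-order (delta-method) bias of the K2P estimator.

    The estimator d(P_hat, Q_hat) is convex, so finite-length monomers measure
    slightly more than the per-site process implies; the multinomial
    (co)variances of the observed proportions give the O(1/L) term.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    g_pp = 2.0 / w1**2
    g_pq = 1.0 / w1**2
    g_qq = 0.5 / w1**2 + 1.0 / w2**2
    var_p = P * (1 - P) / n_sites
    var_q = Q * (1 - Q) / n_sites
    cov = -P * Q / n_sites
    return 0.5 * (g_pp * var_p + 2 * g_pq * cov + g_qq * var_q)


def solve_k2p_proportions(
    target_divergence: float, kappa: float, n_sites: int | None = None
) -> tuple[float, float]:
    """(P, Q) whose K2P distance equals the target, with P/Q == kappa.

    With ``n_sites`` given, the per-site proportions are adjusted for the
    estimator's Jensen bias so that the *measured* K2P distance of an
    ``n_sites``-long monomer is unbiased for the target.
    """
    if target_divergence < 0 or target_divergence >= 0.75:
        raise ValueError("target divergence must lie in [0, 0.75) — K2P saturates beyond")
    if target_divergence == 0:
        return 0.0, 0.0
    q_max = min(0.5, 1.0 / (2.0 * kappa + 1.0)) - 1e-12

    def f(q: float) -> float:
        p = kappa * q
        d = k2p_from_proportions(p, q)
        if n_sites is not None:
            d += _k2p_jensen_bias(p, q, n_sites)
        return d - target_divergence

    q = brentq(f, 0.0, q_max * (1 - 1e-9), xtol=1e-15)
    return kappa * q, q


def mutate_batch(
    consensus_codes: np.ndarray,
    targets: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutate n copies of a coded consensus to per-copy target divergences."""
    n, L = len(targets), len(consensus_codes)
    out = np.tile(consensus_codes, (n, 1))
    n_sites = int((consensus_codes < 4).sum())
    P = np.empty(n)
    Q = np.empty(n)
    for i, t in enumerate(np.asarray(targets, dtype=float)):
        P[i], Q[i] = solve_k2p_proportions(t, kappa, n_sites)
    u = rng.random((n, L))
    half = rng.random((n, L)) < 0.5
    base_ok = out < 4
    ts = (u < P[:, None]) & base_ok
    tv = (u >= P[:, None]) & (u < (P + Q)[:, None]) & base_ok
    out[ts] ^= 2  # A<->G, C<->T
    out[tv] ^= np.where(half[tv], 1, 3).astype(np.uint8)  # the two transversion partners
    return out


def mutate_monomer(
    consensus: str,
    target_divergence: float,
    kappa: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> str:
    """One mutated copy whose expected K2P distance equals the target."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    codes = mutate_batch(encode(consensus), np.array([target_divergence]), kappa, rng)[0]
    return decode(codes)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


class PlacementError(ValueError):
    pass


def _place(
    occupied: list[tuple[int, int]],
    chrom_len: int,
    unit_len: int,
    pad: int,
    rng: np.random.Generator,
    window: tuple[int, int] | None = None,
    max_tries: int = 200,
) -> int:
    lo, hi = window if window else (0, chrom_len)
    hi = min(hi, chrom_len) - unit_len
    lo = max(lo, 0)
    if hi < lo:
        raise PlacementError("array does not fit in its placement window")
    for _ in range(max_tries):
        s = int(rng.integers(lo, hi + 1))
        e = s + unit_len
        if all(e + pad <= os or s >= oe + pad for os, oe in occupied):
            occupied.append((s, e))
            return s
    raise PlacementError("could not place array without overlap")


def _draw_targets(spec: FamilySimSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, _m, _s in spec.divergence_mixture])
    means = np.array([m for _w, m, _s in spec.divergence_mixture])
    sds = np.array([s for _w, _m, s in spec.divergence_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    return np.clip(rng.normal(means[comp], sds[comp]), 0.0, 0.4499)


def _array_chromosomes(spec: FamilySimSpec, chrom_names: list[str], rng: np.random.Generator) -> list[str]:
    mode = spec.placement_mode
    if mode == "single_block":
        return [chrom_names[int(rng.integers(len(chrom_names)))]]
    if mode == "restricted_chromosome":
        c = chrom_names[int(rng.integers(len(chrom_names)))]
        return [c] * spec.n_arrays
    # interspersed / terminal: round-robin over a shuffled chromosome list so
    # the family spans most chromosomes, as the organization classes require
    order = list(rng.permutation(chrom_names))
    if mode == "terminal_blocks" and len(order) > 3:
        order = order[: max(3, spec.n_arrays // 2)]
    return [order[i % len(order)] for i in range(spec.n_arrays)]


def simulate_genome(
    specs: list[FamilySimSpec],
    chromosome_lengths: dict[str, int],
    rng_seed: int | np.random.Generator = 0,
    gc: float = 0.5,
) -> tuple[list[GenomeSequence], TruthTable]:
    """Plant satDNA arrays in i.i.d. background; returns genome plus truth."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    chrom_names = list(chromosome_lengths)
    chrom_codes = {c: _random_dna(n, rng, gc) for c, n in chromosome_lengths.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    mono_rows = []
    array_rows = []
    for spec in specs:
        fam = spec.family
        L = fam.monomer_length
        cons_codes = encode(fam.consensus)
        pad = 5 * L
        cassette = spec.flank_cassette or ""
        clen = len(cassette)
        chroms = _array_chromosomes(spec, chrom_names, rng)
        for a_idx, chrom in enumerate(chroms):
            n_mono = int(rng.integers(spec.array_length_range[0], spec.array_length_range[1] + 1))
            r = int(rng.integers(L))
            strand = "+" if rng.random() < 0.5 else "-"
            targets = _draw_targets(spec, n_mono, rng)
            rot_codes = encode(rotate(fam.consensus, r))
            monomers = mutate_batch(rot_codes, targets, spec.kappa, rng)
            realized = k2p_batch(monomers, rot_codes)
            array_codes = monomers.reshape(-1)
            unit = np.concatenate([encode(cassette), array_codes, encode(cassette)]) if clen else array_codes
            if strand == "-":
                # revcomp in code space: complement is xor 3 (A0<->T3, C1<->G2)
                unit = (unit ^ 3)[::-1].copy()
            clen_chrom = chromosome_lengths[chrom]
            if spec.placement_mode == "terminal_blocks":
                margin = int(0.05 * clen_chrom)
                ends = [(0, margin), (clen_chrom - margin, clen_chrom)]
                if rng.random() < 0.5:
                    ends.reverse()
                try:
                    s = _place(occupied[chrom], clen_chrom, len(unit), pad, rng, ends[0])
                except PlacementError:
                    s = _place(occupied[chrom], clen_chrom, len(unit), pad, rng, ends[1])
            else:
                s = _place(occupied[chrom], clen_chrom, len(unit), pad, rng, None)
            chrom_codes[chrom][s : s + len(unit)] = unit
            arr_start = s + clen
            arr_end = arr_start + n_mono * L
            array_id = f"{fam.family_id}_arr{a_idx}"
            array_rows.append(
                dict(chrom=chrom, start=arr_start, end=arr_end, family=fam.family_id,
                     strand=strand, n_monomers=n_mono, array_id=array_id)
            )
            for i in range(n_mono):
                if strand == "+":
                    ms = arr_start + i * L
                else:
                    ms = arr_start + (n_mono - 1 - i) * L
                mono_rows.append(
                    dict(chrom=chrom, start=ms, end=ms + L, family=fam.family_id,
                         strand=strand, rotation=r, divergence=float(realized[i]),
                         target_divergence=float(targets[i]), array_id=array_id)
                )

    genome = [GenomeSequence(c, decode(chrom_codes[c])) for c in chrom_names]
    truth = TruthTable(
        monomers=pd.DataFrame(mono_rows).sort_values(["chrom", "start"]).reset_index(drop=True),
        arrays=pd.DataFrame(array_rows).sort_values(["chrom", "start"]).reset_index(drop=True),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    families: list[SatFamily],
    expression: pd.DataFrame,
    read_length: int = 100,
    n_background: int = 1000,
    error_rate: float = 0.002,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[dict[str, list[tuple[str, str]]], TruthTable]:
    """Draw reads from family dimers per library under an expression design.

    ``expression`` is indexed by library_id with one integer column per
    family_id (true fragment counts). Reads start uniformly along the dimer
    (both strands), so a fraction spans the monomer junction; per-base
    substitution errors at ``error_rate``; background reads are random DNA.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    fams = {f.family_id: f for f in families}
    for f in families:
        if read_length >= 2 * f.monomer_length:
            raise ValueError(f"read length {read_length} >= dimer length of {f.family_id}")
    libraries: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for lib in expression.index:
        reads: list[tuple[str, str]] = []
        for fam_id in expression.columns:
            count = int(expression.loc[lib, fam_id])
            truth_rows.append(dict(library=lib, family=fam_id, count=count))
            if count == 0:
                continue
            dimer = encode(fams[fam_id].dimer)
            offsets = rng.integers(0, len(dimer) - read_length + 1, size=count)
            mat = np.stack([dimer[o : o + read_length] for o in offsets])
            err = rng.random(mat.shape) < error_rate
            mat[err] = (mat[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
            flip = rng.random(count) < 0.5
            mat[flip] = (mat[flip] ^ 3)[:, ::-1]
            reads.extend((f"{lib}:{fam_id}:{i}", decode(row)) for i, row in enumerate(mat))
        for i in range(n_background):
            reads.append((f"{lib}:bg:{i}", decode(_random_dna(read_length, rng))))
        order = rng.permutation(len(reads))
        libraries[lib] = [reads[i] for i in order]
    return libraries, TruthTable(expression=pd.DataFrame(truth_rows))


def example_expression_design(
    families: list[SatFamily],
    stages=STAGES,
    sexes=("F", "M"),
    n_replicates: int = 2,
    baseline: int = 200,
    peak_stage: tuple[str, str] = ("late_pupa", "M"),
    fold: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A stage x sex design with one planted peak condition.

    Returns (expression counts indexed by library, library metadata). The
    default plants a five-fold elevation in late male pupae, the condition
    where satDNA transcription peaks in the study system.
    """
    rows, meta = {}, []
    for stage in stages:
        for sex in sexes:
            for rep in range(1, n_replicates + 1):
                lib = f"{stage}_{sex}_{rep}"
                level = int(baseline * fold) if (stage, sex) == peak_stage else baseline
                rows[lib] = {f.family_id: level for f in families}
                meta.append(dict(library_id=lib, stage=stage, sex=sex))
    return pd.DataFrame(rows).T, pd.DataFrame(meta).set_index("library_id")


# ---------------------------------------------------------------------------
# presence simulation
# ---------------------------------------------------------------------------

def simulate_presence(
    tree: DatedTree,
    planted_nodes: dict[str, "object"],
    focal_taxon: str,
    rng_seed: int | np.random.Generator = 0,
    coverage_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant a presence/absence table whose qualifying MRCA is a chosen node.

    ``planted_nodes`` maps family_id to a node of ``tree.tree`` (the focal
    leaf itself encodes a single-species family). Present taxa draw coverage
    strictly above the threshold, absent sampled taxa strictly at or below.
    Returns (hits table: taxon, family, query_coverage; truth: family,
    planted_age).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    focal_leaf = tree.tree.find_node_with_taxon_label(focal_taxon)
    if focal_leaf is None:
        raise ValueError(f"focal taxon {focal_taxon!r} not in tree")
    all_nodes = set(tree.tree.preorder_node_iter())
    hit_rows, truth_rows = [], []
    all_taxa = tree.taxa
    for fam, node in planted_nodes.items():
        if node not in all_nodes:
            raise ValueError(f"planted node for {fam} is not a node of the tree")
        present = {focal_taxon}
        if node is not focal_leaf:
            node_leaves = {l.taxon.label for l in node.leaf_iter()}
            if focal_taxon not in node_leaves:
                raise ValueError(f"planted node for {fam} is not ancestral to the focal taxon")
            # one leaf from a child subtree not containing the focal taxon pins
            # the MRCA at exactly the planted node
            other_sides = []
            for child in node.child_nodes():
                leaves = {l.taxon.label for l in child.leaf_iter()}
                if focal_taxon not in leaves:
                    other_sides.extend(sorted(leaves))
            present.add(other_sides[int(rng.integers(len(other_sides)))])
            for leaf in sorted(node_leaves - present):
                if rng.random() < 0.3:
                    present.add(leaf)
        for taxon in all_taxa:
            if taxon == focal_taxon:
                cov = 1.0
            elif taxon in present:
                cov = float(rng.uniform(coverage_threshold + 0.05, 1.0))
            else:
                cov = float(rng.uniform(0.0, coverage_threshold))  # below/at threshold
            hit_rows.append(dict(taxon=taxon, family=fam, query_coverage=cov))
        truth_rows.append(dict(family=fam, planted_age=tree.node_age(node), n_present=len(present)))
    return pd.DataFrame(hit_rows), pd.DataFrame(truth_rows)
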
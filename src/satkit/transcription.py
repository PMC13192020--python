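"""SatDNA transcription quantification against head-to-tail dimer references.

A read is counted for a family if it matches the family's dimer (consensus
concatenated with itself — so junction-spanning reads align without clipping)
end-to-end, ungapped, at any offset on either strand, with at most
``mismatch_limit`` mismatches (default 1). Counts are FPKM-normalized:

    FPKM = C_s * 1e9 / (L_s * N)

with C_s the fragment count for satellite s, L_s the dimer length (bp) and N
the library-size denominator in fragments. Because copy number varies wildly
between satellites, FPKM here is valid for longitudinal comparison (one
family across stages/sexes), not for ranking families against each other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from satkit.divergence import encode
from satkit.records import SatFamily

logger = logging.getLogger("satkit")


def _window_matrix(dimer_codes: np.ndarray, read_len: int) -> np.ndarray:
    n_off = len(dimer_codes) - read_len + 1
    return np.stack([dimer_codes[o : o + read_len] for o in range(n_off)])


def _min_mismatches(batch: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Per-read minimum mismatch count over all windows (vectorized)."""
    # (reads, 1, L) vs (1, windows, L) -> mismatch counts per (read, window)
    mm = (batch[:, None, :] != windows[None, :, :]).sum(axis=2)
    return mm.min(axis=1)


def read_matches_dimer(read: str, family: SatFamily, mismatch_limit: int = 1) -> bool:
    """Brute-force check of one read against one family's dimer."""
    codes = encode(read)
    L = len(codes)
    dimer = encode(family.dimer)
    if L > len(dimer):
        return False
    for probe in (codes, (np.where(codes < 4, codes ^ 3, codes))[::-1]):
        for o in range(len(dimer) - L + 1):
            if int((dimer[o : o + L] != probe).sum()) <= mismatch_limit:
                return True
    return False


def count_matching_reads(
    reads: list[tuple[str, str]] | list[str],
    families: list[SatFamily],
    mismatch_limit: int = 1,
    batch_size: int = 512,
) -> pd.DataFrame:
    """Per-family fragment counts for one library.

    ``reads`` are (id, sequence) pairs or plain sequences; a fragment may also
    be given as (id, seq1, seq2) for paired ends, counting once if either
    mate matches. A fragment counts at most once per family but may count for
    several families (all-alignments semantics). Reads longer than a dimer
    are skipped for that family with a logged count.
    """
    frags: list[list[str]] = []
    for r in reads:
        if isinstance(r, str):
            frags.append([r])
        else:
            frags.append([s for s in r[1:] if s])
    counts = {f.family_id: 0 for f in families}
    n_skipped = 0

    # group mate sequences by length for vectorized matching
    seq_index: dict[int, list[tuple[int, np.ndarray]]] = {}
    for fi, mates in enumerate(frags):
        for s in mates:
            seq_index.setdefault(len(s), []).append((fi, encode(s)))

    for fam in families:
        dimer = encode(fam.dimer)
        matched = np.zeros(len(frags), dtype=bool)
        for length, items in seq_index.items():
            if length > len(dimer):
                n_skipped += len(items)
                continue
            windows = _window_matrix(dimer, length)
            idx = np.array([fi for fi, _ in items])
            mat = np.stack([c for _, c in items])
            rc = np.where(mat < 4, mat ^ 3, mat)[:, ::-1]
            for start in range(0, len(mat), batch_size):
                sl = slice(start, start + batch_size)
                mm_f = _min_mismatches(mat[sl], windows)
                mm_r = _min_mismatches(rc[sl], windows)
                ok = np.minimum(mm_f, mm_r) <= mismatch_limit
                matched[idx[sl][ok]] = True
        counts[fam.family_id] = int(matched.sum())
    if n_skipped:
        logger.info("count_matching_reads: %d read/family pairs skipped (read longer than dimer)", n_skipped)
    return pd.DataFrame(
        [{"family": f.family_id, "count": counts[f.family_id], "dimer_length": 2 * f.monomer_length} for f in families]
    )


def fpkm(count: int, feature_length: int, library_size: int) -> float:
    """Fragments per kilobase of feature per million library fragments."""
    if feature_length <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("empty library: library size must be positive")
    return count * 1e9 / (feature_length * library_size)


def quantify_libraries(
    libraries: dict[str, list[tuple[str, str]]],
    families: list[SatFamily],
    meta: pd.DataFrame | None = None,
    mismatch_limit: int = 1,
    library_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Count and FPKM-normalize every library.

    ``meta`` (indexed by library_id) may carry ``stage`` and ``sex`` columns.
    ``library_sizes`` overrides the FPKM denominator N per library (e.g. with
    genome-mapped fragment counts); the default N is the total number of
    fragments in the library.
    """
    rows = []
    for lib, reads in libraries.items():
        N = library_sizes[lib] if library_sizes else len(reads)
        table = count_matching_reads(reads, families, mismatch_limit)
        for _, r in table.iterrows():
            row = dict(
                family=r["family"],
                library=lib,
                count=int(r["count"]),
                N=N,
                fpkm=fpkm(int(r["count"]), int(r["dimer_length"]), N),
            )
            if meta is not None and lib in meta.index:
                row["stage"] = meta.loc[lib, "stage"]
                row["sex"] = meta.loc[lib, "sex"]
            rows.append(row)
    return pd.DataFrame(rows)


def expression_profile(records: pd.DataFrame, min_depth: int = 0) -> pd.DataFrame:
    """Per family x stage x sex: mean FPKM, sample SD, replicate count.

    Libraries whose denominator N falls below ``min_depth`` are excluded with
    a log line (a simple stand-in for library-level QC). With a single
    replicate the SD is reported as missing, never as zero.
    """
    df = records.copy()
    shallow = df["N"] < min_depth
    if shallow.any():
        dropped = sorted(df.loc[shallow, "library"].unique())
        logger.info("expression_profile: excluding low-depth libraries %s", dropped)
        df = df[~shallow]
    grouped = (
        df.groupby(["family", "stage", "sex"], sort=True)["fpkm"]
        .agg(mean_fpkm="mean", sd_fpkm=lambda x: x.std(ddof=1), n_replicates="count")
        .reset_index()
    )
    return grouped


def peak_condition(profile: pd.DataFrame, family: str) -> tuple[str, str]:
    """(stage, sex) with the highest mean FPKM for one family."""
    sub = profile[profile["family"] == family]
    top = sub.loc[sub["mean_fpkm"].idxmax()]
    return top["stage"], top["sex"]


def rank_families(profile: pd.DataFrame, force: bool = False) -> pd.DataFrame:
    """Cross-family FPKM ranking — refused unless forced.

    FPKM is not comparable between satellites with different copy numbers;
    this guard documents that non-property instead of silently ranking.
    """
    if not force:
        raise ValueError(
            "FPKM values are valid for longitudinal (within-family) comparison only; "
            "pass force=True to rank families anyway"
        )
    return (
        profile.groupby("family")["mean_fpkm"].max().sort_values(ascending=False).reset_index()
    )
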
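import itertools

import numpy as np
import pytest

from satkit.alignment import alignment_divergence
from satkit.annotate import build_arrays, find_monomers, summarize_satellitome
from satkit.records import GenomeSequence, MonomerHit, SatFamily, revcomp, rotate
from satkit.simulate import FamilySimSpec, mutate_monomer, simulate_genome
from tests.conftest import random_dna


def flank(n, seed):
    return random_dna(n, seed)


class TestFindMonomers:
    def test_exact_tandem_five_hits(self, family):
        g = GenomeSequence("chr1", flank(800, 1) + family.consensus * 5 + flank(800, 2))
        hits = find_monomers(g, family)
        assert len(hits) == 5
        assert all((h.divergence, h.rotation, h.strand) == (0.0, 0, "+") for h in hits)
        assert hits[0].start == 800 and hits[-1].end == 800 + 5 * 142

    def test_reverse_complement_three_hits(self, family):
        g = GenomeSequence("chr1", flank(500, 3) + revcomp(family.consensus * 3) + flank(500, 4))
        hits = find_monomers(g, family)
        assert len(hits) == 3
        assert all(h.strand == "-" and h.divergence == 0.0 for h in hits)

    def test_strand_symmetry(self, family):
        """Annotating the reverse-complemented genome mirrors coordinates.

        Mirror agreement is checked to within a few bp: background bases that
        happen to match the consensus lattice at an array edge are genuinely
        indistinguishable from array sequence, and the two orientations may
        resolve that ambiguity differently.
        """
        seq = flank(400, 5) + family.consensus * 4 + flank(300, 6)
        fwd = find_monomers(GenomeSequence("c", seq), family)
        rev = find_monomers(GenomeSequence("c", revcomp(seq)), family)
        n = len(seq)
        assert len(fwd) == len(rev) == 4
        assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}
        mirrored = sorted((n - h.end, n - h.start) for h in rev)
        for (fs, fe), (ms, me) in zip(sorted((h.start, h.end) for h in fwd), mirrored):
            assert abs(fs - ms) <= 8 and abs(fe - me) <= 8

    def test_rotated_consensus_same_spans(self, family):
        seq = flank(400, 107) + family.consensus * 4 + flank(400, 108)
        g = GenomeSequence("c", seq)
        base = find_monomers(g, family)
        rot_fam = SatFamily("rot", rotate(family.consensus, 37))
        rot = find_monomers(g, rot_fam)
        span = (min(h.start for h in base), max(h.end for h in base))
        rspan = (min(h.start for h in rot), max(h.end for h in rot))
        assert abs(span[0] - rspan[0]) <= 142 and abs(span[1] - rspan[1]) <= 142
        # a hit beginning at consensus offset r begins at offset r-37 of the
        # rotated consensus
        assert all((h.rotation + 37) % 142 == base[0].rotation for h in rot[1:-1] or rot)

    def test_rotated_array_reports_rotation(self, family):
        r = 55
        g = GenomeSequence("c", flank(300, 9) + rotate(family.consensus, r) * 4 + flank(300, 10))
        hits = find_monomers(g, family)
        assert len(hits) == 4
        assert all(h.rotation == r for h in hits)

    def test_high_divergence_not_reported(self, family, rng):
        bad = mutate_monomer(family.consensus, 0.60, rng=rng)
        g = GenomeSequence("c", flank(400, 11) + bad + flank(400, 12))
        assert find_monomers(g, family) == []

    def test_hits_non_overlapping_per_family(self, family):
        spec = FamilySimSpec(family, "interspersed", n_arrays=30, array_length_range=(1, 6),
                             divergence_mixture=((1.0, 0.15, 0.05),))
        genome, _ = simulate_genome([spec], {"c1": 200_000, "c2": 200_000}, 8)
        hits = find_monomers(genome, family)
        by_chrom = {}
        for h in hits:
            by_chrom.setdefault(h.seq_id, []).append(h)
        for hs in by_chrom.values():
            hs.sort(key=lambda h: h.start)
            assert all(a.end <= b.start for a, b in zip(hs, hs[1:]))

    def test_empty_genome_warns(self, family, caplog):
        with caplog.at_level("WARNING", logger="satkit"):
            assert find_monomers([], family) == []

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError, match="20 bp"):
            find_monomers([], SatFamily("x", "ACGTACGTAC"))

    def test_exhaustive_oracle_small_genome(self):
        """On a <=5-kb genome, hits match brute force over all positions,
        rotations and strands."""
        fam = SatFamily("f", random_dna(60, 21))
        L = 60
        parts = [
            flank(700, 22), fam.consensus * 3, flank(650, 23),
            revcomp(rotate(fam.consensus, 20) * 2), flank(700, 24),
            mutate_monomer(fam.consensus, 0.10, rng=1), flank(600, 25),
        ]
        seq = "".join(parts)
        g = GenomeSequence("c", seq)
        hits = find_monomers(g, fam, max_divergence=0.30)

        oracle = []
        for pos in range(len(seq) - L + 1):
            window = seq[pos : pos + L]
            best = min(
                min(sum(a != b for a, b in zip(window, rotate(q, r))) / L for r in range(L))
                for q in (fam.consensus, revcomp(fam.consensus))
            )
            if best <= 0.30:
                oracle.append((pos, best))
        # greedy selection of non-overlapping oracle windows, best first
        oracle.sort(key=lambda t: (t[1], t[0]))
        chosen = []
        for pos, d in oracle:
            if all(abs(pos - p) >= L for p, _ in chosen):
                chosen.append((pos, d))
        assert sorted(h.start for h in hits) == sorted(p for p, _ in chosen)


class TestBuildArrays:
    def hit(self, start, family_id="f", seq_id="c", strand="+", L=142):
        return MonomerHit(family_id, seq_id, start, start + L, strand, 0, 0.0, L)

    def test_adjacent_hits_merge(self):
        hits = [self.hit(i * 142) for i in range(5)]
        arrays = build_arrays(hits)
        assert len(arrays) == 1 and arrays[0].n_monomers == 5

    def test_distant_hits_split(self):
        hits = [self.hit(0), self.hit(10_000)]
        assert len(build_arrays(hits, gap_tolerance=142)) == 2

    def test_monomer_conservation(self, family):
        spec = FamilySimSpec(family, "interspersed", n_arrays=20, array_length_range=(1, 5))
        genome, _ = simulate_genome([spec], {"c1": 300_000}, 3)
        hits = find_monomers(genome, family)
        arrays = build_arrays(hits)
        assert sum(a.n_monomers for a in arrays) == len(hits)

    def test_strand_split(self):
        hits = [self.hit(0), self.hit(142, strand="-")]
        assert len(build_arrays(hits)) == 2

    def test_twelve_planted_arrays_reconstructed(self, family):
        spec = FamilySimSpec(family, "restricted_chromosome", n_arrays=12,
                             array_length_range=(2, 9), divergence_mixture=((1.0, 0.05, 0.02),))
        genome, truth = simulate_genome([spec], {"cY": 400_000}, 5)
        arrays = build_arrays(find_monomers(genome, family))
        assert len(arrays) == 12
        got = sorted((a.start, a.end) for a in arrays)
        want = sorted(zip(truth.arrays.start, truth.arrays.end))
        for (gs, ge), (ws, we) in zip(got, want):
            assert abs(gs - ws) <= 10 and abs(ge - we) <= 10

    def test_unsorted_input_logged(self, caplog):
        hits = [self.hit(142), self.hit(0)]
        with caplog.at_level("INFO", logger="satkit"):
            arrays = build_arrays(hits)
        assert sum(a.n_monomers for a in arrays) == 2


class TestSummary:
    def test_empty_annotation(self):
        table = summarize_satellitome([], [GenomeSequence("c1", "ACGT" * 100)])
        assert table.empty

    def test_genome_fraction_arithmetic(self, family):
        g = GenomeSequence("chr1", flank(5000, 31) + family.consensus * 5 + flank(100_000 - 5000 - 710, 32))
        assert g.length == 100_000
        arrays = build_arrays(find_monomers(g, family))
        table = summarize_satellitome(arrays, [g])
        assert table.loc["TmSat01", "genome_fraction"] == pytest.approx(710 / 100_000)
        assert table.loc["TmSat01", "n_monomers"] == 5
        assert bool(table.loc["TmSat01", "on_chr1"]) is True

    def test_counts_match_truth_on_clean_input(self, family):
        spec = FamilySimSpec(family, "interspersed", n_arrays=15, array_length_range=(1, 4),
                             divergence_mixture=((1.0, 0.02, 0.01),))
        genome, truth = simulate_genome([spec], {"c1": 200_000, "c2": 200_000}, 6)
        arrays = build_arrays(find_monomers(genome, family))
        table = summarize_satellitome(arrays, genome)
        assert table.loc["TmSat01", "n_monomers"] == len(truth.monomers)
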
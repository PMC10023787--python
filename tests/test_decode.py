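"""Demultiplexing, code extraction/assignment and streaming read counting."""

import numpy as np
import pytest

from tdel.codes import AMBIGUOUS, ASSIGNED
from tdel.decode import (
    assign_code,
    count_reads,
    demultiplex,
    extract_code,
)
from tdel.dna import hamming
from tdel.errors import ConfigError, FastqFormatError
from tdel.simulate import generate_fastq, simulate_selection, random_binding_model, write_fastq


def brute_force_demux(index_seq, index_table, max_mismatch):
    """Exhaustive nearest-index scan."""
    dists = {s: hamming(index_seq, seq) for s, seq in index_table.items()}
    best = min(dists.values())
    if best > max_mismatch:
        return None
    winners = [s for s, d in dists.items() if d == best]
    return winners[0] if len(winners) == 1 else None


class TestDemultiplex:
    def test_exact_match(self, small_scheme):
        read = small_scheme.read_template("target", "A", small_scheme.codebooks["A"].codes[0])
        sample, reason = demultiplex(read, small_scheme.index_table,
                                     max_mismatch=0, region=small_scheme.index_region)
        assert (sample, reason) == ("target", ASSIGNED)

    def test_one_mismatch_agrees_with_brute_force(self, small_scheme):
        table = small_scheme.index_table
        region = small_scheme.index_region
        rng = np.random.default_rng(5)
        for sample, index in table.items():
            for pos in range(len(index)):
                base = "ACGT"[rng.integers(0, 4)]
                corrupted = index[:pos] + base + index[pos + 1 :]
                read = corrupted + "A" * 40
                got, _ = demultiplex(read, table, max_mismatch=1, region=region)
                assert got == brute_force_demux(corrupted, table, 1)

    def test_equidistant_read_is_ambiguous(self):
        table = {"s1": "AAAA", "s2": "AATT"}
        # "AAAT" is at distance 1 from both
        sample, reason = demultiplex("AAAT" + "C" * 20, table, max_mismatch=1, region=(0, 4))
        assert sample is None and reason == AMBIGUOUS

    def test_duplicate_index_sequences_rejected(self):
        with pytest.raises(ConfigError):
            demultiplex("AAAA", {"s1": "AAAA", "s2": "AAAA"}, 1, (0, 4))


class TestExtractCode:
    def test_fixed_mode_round_trip(self, small_scheme, small_library):
        for name, seq, _ in generate_fastq(
            np.ones(small_library.shape, dtype=int), small_scheme, small_library, "pre", 0.0
        ):
            channel = name.split(":")[1]
            code, reason = extract_code(seq, small_scheme, channel)
            assert reason == ASSIGNED
            assert code in small_scheme.codebooks[channel]

    def test_short_read_fails(self, small_scheme):
        code, reason = extract_code("ACGT", small_scheme, "A")
        assert code is None and reason == "no_code"

    def test_anchored_mode_matches_fixed_mode_on_unshifted_reads(self, small_scheme, small_library):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, small_library.shape)
        for name, seq, _ in generate_fastq(
            counts, small_scheme, small_library, "target", 0.01, seed=2
        ):
            channel = name.split(":")[1]
            fixed, _ = extract_code(seq, small_scheme, channel, anchored=False)
            anchored, _ = extract_code(seq, small_scheme, channel, anchored=True,
                                       flank_mismatch=1)
            f0, f1 = small_scheme.flank_region
            if hamming(seq[f0:f1], small_scheme.flanks[channel]) <= 1:
                assert anchored == fixed


class TestAssignCode:
    def test_delegates_to_codebook(self, small_scheme):
        cb = small_scheme.codebooks["B"]
        code = cb.codes[0]
        assert assign_code(code, cb, 0) == (cb.id_of(code), ASSIGNED)


class TestCountReads:
    def _simulated_records(self, scheme, library, error_rate, seed, pool=20_000):
        model = random_binding_model(library.shape, seed=seed)
        truth = simulate_selection(np.ones(library.shape), model, pool, seed=seed + 1)
        reads = generate_fastq(
            truth.post_counts, scheme, library, "target", error_rate, seed=seed + 2
        )
        return truth, reads

    def test_noiseless_counts_equal_ground_truth(self, small_scheme, small_library):
        truth, reads = self._simulated_records(small_scheme, small_library, 0.0, seed=10)
        table = count_reads(reads, small_scheme)
        for role in "ABC":
            expected = {
                bb.id: int(k)
                for bb, k in zip(small_library.sub(role).members, truth.marginal(role))
                if k > 0
            }
            assert table.channel("target", role) == expected
        assert table.is_conserved()

    def test_empty_input(self, small_scheme):
        table = count_reads([], small_scheme)
        assert table.total_reads == 0
        assert table.to_frame().empty

    def test_order_invariance(self, small_scheme, small_library):
        _, reads = self._simulated_records(small_scheme, small_library, 0.003, seed=3, pool=2_000)
        records = list(reads)
        shuffled = [records[i] for i in np.random.default_rng(0).permutation(len(records))]
        a = count_reads(records, small_scheme).to_frame()
        b = count_reads(shuffled, small_scheme).to_frame()
        assert a.equals(b)

    def test_conservation_with_errors(self, small_scheme, small_library):
        _, reads = self._simulated_records(small_scheme, small_library, 0.02, seed=4, pool=5_000)
        table = count_reads(reads, small_scheme)
        assert table.is_conserved()
        assert table.total_reads == 15_000

    def test_misassignment_below_two_error_binomial_bound(self, small_scheme, small_library):
        """At eps=0.005 and code min-distance >= 3 with mm=1, only reads with
        >= 2 errors inside the code region can be misassigned."""
        eps = 0.005
        truth, reads = self._simulated_records(small_scheme, small_library, eps, seed=6,
                                               pool=10_000)
        wrong = 0
        assigned = 0
        for name, seq, _ in reads:
            channel, src = name.split(":")[1:3]
            cb = small_scheme.codebooks[channel]
            assert cb.min_distance >= 3
            c0, c1 = small_scheme.code_region
            code_id, reason = cb.assign(seq[c0:c1], 1)
            if reason == ASSIGNED:
                assigned += 1
                if code_id != src:
                    wrong += 1
        length = small_scheme.code_length
        p_two_err = 1 - (1 - eps) ** length - length * eps * (1 - eps) ** (length - 1)
        assert assigned > 0
        assert wrong / assigned <= p_two_err

    def test_fastq_file_and_gzip_equivalence(self, tmp_path, small_scheme, small_library):
        _, reads = self._simulated_records(small_scheme, small_library, 0.005, seed=8, pool=2_000)
        records = list(reads)
        plain = tmp_path / "reads.fastq"
        gz = tmp_path / "reads.fastq.gz"
        write_fastq(records, plain)
        write_fastq(records, gz)
        in_memory = count_reads(records, small_scheme).to_frame()
        from_plain = count_reads(plain, small_scheme).to_frame()
        from_gz = count_reads(gz, small_scheme).to_frame()
        assert in_memory.equals(from_plain)
        assert in_memory.equals(from_gz)

    def test_malformed_fastq_fails_fast_with_record_number(self, tmp_path, small_scheme):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # quality shorter than sequence
        with pytest.raises(FastqFormatError) as exc:
            count_reads(path, small_scheme)
        assert exc.value.record_number == 1
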
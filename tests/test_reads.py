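"""Read processing: merging, trimming, matching, counting."""

import pytest

from sortscreen import (
    ProcessingParams,
    ReadPair,
    ScreenConfig,
    count_reads,
    merge_pair,
    preset_model,
    simulate_screen,
    translate_and_match,
    trim_adapters,
)
from sortscreen.reads import Merged, Reject
from sortscreen.screen import revcomp, write_fastq

Q40 = chr(33 + 40)


def make_pair(template: str, read_len: int, q1: str | None = None,
              q2: str | None = None) -> ReadPair:
    r1 = template[:read_len]
    r2 = revcomp(template)[:read_len]
    return ReadPair(r1, r2, q1 or Q40 * read_len, q2 or Q40 * read_len)


def brute_force_best_overlap(r1: str, rc2: str, min_overlap: int):
    """Independent scorer: try every relative placement by string ops."""
    best = None
    for off in range(-len(rc2) + 1, len(r1)):
        lo, hi = max(0, off), min(len(r1), off + len(rc2))
        ov = hi - lo
        if ov < min_overlap:
            continue
        matches = sum(r1[i] == rc2[i - off] for i in range(lo, hi))
        score = 2 * matches - ov
        if best is None or (score, ov) > best[:2]:
            best = (score, ov, off)
    return best


class TestMergePair:
    def test_exact_overlap_recovers_template(self):
        template = "ACGTACGGATCCTTAGCCGATCGGATATCGCGATTACCGGATGCATGCATCGGATCGTAT"
        assert len(template) == 60
        pair = make_pair(template, 50)  # 40-nt overlap
        merged = merge_pair(pair, min_overlap=10)
        assert isinstance(merged, Merged)
        assert merged.seq == template

    def test_conflict_higher_quality_base_wins(self):
        # disagree at one overlap position: A(Q40) on r1 vs C(Q10) on r2
        template = "ACGGATCCTTAGCCGATCGGATAT"
        r1 = template[:16]
        rc2 = template[8:10] + "C" + template[11:]  # template[10] 'A' -> 'C'
        assert template[10] == "A"
        r2 = revcomp(rc2)
        q_low = chr(33 + 10)
        pair = ReadPair(r1, r2, Q40 * len(r1), q_low * len(r2))
        merged = merge_pair(pair, min_overlap=6)
        assert isinstance(merged, Merged)
        assert merged.seq == template  # r1's high-quality base won

    def test_matches_brute_force_offset(self):
        template = "ACGGATCCTTAGCCGATCGGATATCGCGATTACCGG"
        pair = make_pair(template, 24)
        rc2 = revcomp(pair.r2_seq)
        oracle = brute_force_best_overlap(pair.r1_seq, rc2, 10)
        merged = merge_pair(pair, min_overlap=10)
        assert isinstance(merged, Merged)
        assert len(merged.seq) == len(template) and merged.seq == template
        assert oracle[2] == len(template) - 24  # expected placement

    def test_no_overlap_rejected(self):
        pair = ReadPair("A" * 30, "C" * 30, Q40 * 30, Q40 * 30)
        # revcomp("C"*30) = "G"*30: no scoring overlap against "A"*30
        assert merge_pair(pair, min_overlap=10) == Reject("merge_fail")

    def test_low_mean_quality_rejected(self):
        template = "ACGTACGGATCCTTAGCCGATCGGATATCGCG"
        q_low = chr(33 + 12)
        pair = make_pair(template, 24, q1=q_low * 24, q2=q_low * 24)
        assert merge_pair(pair, q_threshold=30) == Reject("merge_fail")

    def test_malformed_quality_is_error_not_reject(self):
        with pytest.raises(ValueError):
            ReadPair("ACGT", "ACGT", Q40 * 3, Q40 * 4)

    def test_phred64_rejected_loudly(self):
        with pytest.raises(ValueError, match="Phred"):
            ReadPair("ACGT", "ACGT", "hhhh", "hhhh")  # Phred+64 Q40


class TestTrimAdapters:
    A5, A3 = "ACACTCTTTC", "AGATCGGAAG"

    def test_exact_flanks(self):
        insert = "GACTACGGATCC"
        read = self.A5 + insert + self.A3
        assert trim_adapters(read, self.A5, self.A3) == insert

    def test_one_mismatch_in_adapter5_still_found(self):
        insert = "GACTACGGATCC"
        a5_mut = "T" + self.A5[1:]
        read = a5_mut + insert + self.A3
        assert trim_adapters(read, self.A5, self.A3, max_mismatch=1) == insert

    def test_exhaustive_alignment_oracle_on_toy(self):
        # 10-nt toy: brute-force every placement of the 4-nt adapters
        a5, a3 = "ACGT", "TTAA"
        read = "G" + a5 + "CC" + a3  # leading junk base, 2-nt insert
        insert = trim_adapters(read, a5, a3, max_mismatch=0)
        positions5 = [i for i in range(len(read) - 3)
                      if sum(a != b for a, b in zip(read[i:i + 4], a5)) == 0]
        positions3 = [i for i in range(len(read) - 3)
                      if sum(a != b for a, b in zip(read[i:i + 4], a3)) == 0]
        assert insert == read[positions5[0] + 4: positions3[-1]] == "CC"

    def test_missing_adapter3_rejected(self):
        read = self.A5 + "GACTACGGATCC"
        assert trim_adapters(read, self.A5, self.A3) == Reject("adapter_fail")


class TestTranslateAndMatch:
    def test_parent_dna_is_wt(self, lat_y226_library):
        from sortscreen import reverse_translate

        dna = reverse_translate(lat_y226_library.spec)
        assert translate_and_match(dna, lat_y226_library) == "WT"

    def test_single_codon_substitution(self, lat_y226_library):
        from sortscreen import reverse_translate

        dna = reverse_translate(lat_y226_library.spec)
        i = 225 - 219  # D225 codon
        mutant = dna[: 3 * i] + "AAG" + dna[3 * i + 3:]
        assert translate_and_match(mutant, lat_y226_library) == "D225K"

    def test_stop_at_randomized_position(self, lat_y226_library):
        from sortscreen import reverse_translate

        dna = reverse_translate(lat_y226_library.spec)
        mutant = dna[:0] + "TAG" + dna[3:]
        assert translate_and_match(mutant, lat_y226_library) == "E219*"

    def test_frame_fail(self, lat_y226_library):
        assert translate_and_match("ACGTACG", lat_y226_library) == Reject("frame_fail")

    def test_multi_mutant_rejected(self, lat_y226_library):
        from sortscreen import reverse_translate

        dna = reverse_translate(lat_y226_library.spec)
        mutant = "AAG" + dna[3:6] + "AAG" + dna[9:]
        assert translate_and_match(mutant, lat_y226_library) == Reject("multi_mutant")

    def test_ambiguous_base_unmatched(self, lat_y226_library):
        dna = "N" * (3 * len(lat_y226_library.parent_protein))
        assert translate_and_match(dna, lat_y226_library) == Reject("unmatched")


class TestCountReads:
    def _params(self, cfg):
        return ProcessingParams(adapter5=cfg.adapter5, adapter3=cfg.adapter3)

    def test_error_free_reads_reproduce_allocation(self, tmp_path, lat_y226_library):
        """With no sequencing errors, counting equals the simulator's read
        allocation exactly (oracle equivalence)."""
        model = preset_model("zap70-like", rng_seed=1)
        cfg = ScreenConfig(n_cells=20_000, reads_per_variant=3,
                           seq_error_rate=0.0, rng_seed=9)
        res = simulate_screen(lat_y226_library, model, cfg)
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        alloc = write_fastq(res, lat_y226_library, cfg, r1, r2, "sorted")
        table = count_reads(r1, r2, lat_y226_library, self._params(cfg))
        assert table.counts == alloc
        assert sum(table.rejected.values()) == 0
        table.check()

    def test_empty_fastq(self, tmp_path, lat_y226_library):
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        r1.write_text("")
        r2.write_text("")
        cfg = ScreenConfig()
        table = count_reads(r1, r2, lat_y226_library, self._params(cfg))
        assert table.total_reads == 0
        assert all(v == 0 for v in table.counts.values())

    def test_foreign_reads_are_unmatched(self, tmp_path, lat_y226_library):
        cfg = ScreenConfig()
        foreign = "GGG" * len(lat_y226_library.parent_protein)
        frag = cfg.adapter5 + foreign + cfg.adapter3
        r1s, r2s = frag[:75], revcomp(frag)[:75]
        q = Q40 * 75
        (tmp_path / "R1.fastq").write_text(f"@x/1\n{r1s}\n+\n{q}\n")
        (tmp_path / "R2.fastq").write_text(f"@x/2\n{r2s}\n+\n{q}\n")
        table = count_reads(tmp_path / "R1.fastq", tmp_path / "R2.fastq",
                            lat_y226_library, self._params(cfg))
        # foreign insert translates to poly-G: >1 difference from parent
        assert table.rejected["multi_mutant"] + table.rejected["unmatched"] == 1
        assert sum(table.counts.values()) == 0

    def test_accounting_identity_with_errors(self, tmp_path, lat_y226_library):
        model = preset_model("zap70-like", rng_seed=1)
        cfg = ScreenConfig(n_cells=20_000, reads_per_variant=3,
                           seq_error_rate=0.02, rng_seed=9)
        res = simulate_screen(lat_y226_library, model, cfg)
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        write_fastq(res, lat_y226_library, cfg, r1, r2, "unsorted")
        table = count_reads(r1, r2, lat_y226_library, self._params(cfg))
        table.check()
        assert table.total_reads == 3 * len(lat_y226_library.members)

    @pytest.mark.parametrize("rates", [(0.0, 0.01), (0.01, 0.05)])
    def test_error_rate_degrades_exact_matches(self, tmp_path, lat_y226_library, rates):
        """Raising the substitution rate never increases exact-match counts."""
        model = preset_model("flat")
        totals = {}
        for err in rates:
            cfg = ScreenConfig(n_cells=20_000, reads_per_variant=3,
                               seq_error_rate=err, rng_seed=21)
            res = simulate_screen(lat_y226_library, model, cfg)
            r1 = tmp_path / f"R1_{err}.fastq"
            r2 = tmp_path / f"R2_{err}.fastq"
            write_fastq(res, lat_y226_library, cfg, r1, r2, "unsorted")
            table = count_reads(r1, r2, lat_y226_library, self._params(cfg))
            totals[err] = sum(table.counts.values())
        lo, hi = rates
        assert totals[hi] <= totals[lo]
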
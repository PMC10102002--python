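import numpy as np
import pytest

from tdmdscreen.duplex_fold import fold_duplex
from tdmdscreen.io_formats import Transcript
from tdmdscreen.preprocess import preprocess_reads
from tdmdscreen.screen import DEFAULT_CONFIG, classify_tdmd
from tdmdscreen.synthetic import (
    PlantingError,
    SimConfig,
    TriggerSpec,
    build_scenario,
    gen_mirnome,
    gen_transcriptome,
    plant_trigger,
    sim_clash_reads,
    sim_mirna_count_matrix,
    sim_mrna_counts,
    sim_smallrna_reads,
)

from ._scenarios import SMALL


class TestGenerators:
    def test_mirnome_deterministic_and_prefix_unique(self):
        a = gen_mirnome(50, seed=7)
        b = gen_mirnome(50, seed=7)
        assert a == b
        assert len({m.sequence[:18] for m in a}) == 50
        assert all(21 <= len(m.sequence) <= 23 for m in a)

    def test_mirnome_empty(self):
        assert gen_mirnome(0, seed=1) == []

    def test_transcriptome_has_utr_annotations(self):
        txs = gen_transcriptome(20, seed=3)
        assert all(t.cds_end is not None and 0 < t.cds_end < len(t.sequence) for t in txs)


class TestPlantTrigger:
    def _any(self, spec, seed=11):
        mirnas = gen_mirnome(20, seed)
        t = gen_transcriptome(1, seed)[0]
        rng = np.random.default_rng(0)
        last = None
        for m in mirnas:
            try:
                return m, *plant_trigger(t, m, spec, rng=rng)
            except PlantingError as exc:
                last = exc
        raise AssertionError(f"no miRNA satisfied {spec}: {last}")

    def test_planted_trigger_classifies_as_candidate(self):
        m, t2, (a, b) = self._any(TriggerSpec("trigger", loop_len=4, loop_strand="target"))
        window = t2.sequence[a : b + 25]
        call = classify_tdmd(fold_duplex(m.sequence, window))
        assert call.is_candidate
        assert call.dg <= DEFAULT_CONFIG.dg_max - 2

    def test_perfect_complement_decoy_fails_central(self):
        m, t2, (a, b) = self._any(TriggerSpec("decoy_perfect"))
        call = classify_tdmd(fold_duplex(m.sequence, t2.sequence[a : b + 25]))
        assert not call.central_ok and not call.is_candidate

    def test_seed_only_decoy_fails_three_prime(self):
        m, t2, (a, b) = self._any(TriggerSpec("decoy_seed_only"))
        call = classify_tdmd(fold_duplex(m.sequence, t2.sequence[a : b + 25]))
        assert not call.three_prime_ok and not call.is_candidate

    def test_energy_decoy_fails_energy_only_at_structure_level(self):
        m, t2, (a, b) = self._any(TriggerSpec("decoy_energy"))
        call = classify_tdmd(fold_duplex(m.sequence, t2.sequence[a : b + 25]))
        assert not call.energy_ok and not call.is_candidate

    def test_unannotated_transcript_rejected(self):
        m = gen_mirnome(1, 5)[0]
        t = Transcript("t", "t", "ACGU" * 100, cds_end=None)
        with pytest.raises(PlantingError):
            plant_trigger(t, m, TriggerSpec("trigger"))


class TestScenario:
    def test_structural_contracts_hold_across_seeds(self):
        """Planted triggers classify as candidates and every decoy fails its
        designated criterion, re-checked here independently of the
        generation-time assertions."""
        for seed in range(3):
            sc = build_scenario(SMALL, seed=seed)
            tx = {t.id: t for t in sc.transcripts}
            assert len(sc.truth.triggers) == 5 and len(sc.truth.decoys) == 10
            for site in sc.planted:
                m = next(mm for mm in sc.mirnas if mm.id == site.mirna_id)
                window = tx[site.transcript_id].sequence[
                    site.site_start : site.site_end + 25
                ]
                call = classify_tdmd(fold_duplex(m.sequence, window))
                if site.failed_criterion in (None, "abundance", "enrichment"):
                    assert call.is_candidate
                else:
                    flag = {
                        "seed": call.seed_ok,
                        "three_prime": call.three_prime_ok,
                        "central": call.central_ok,
                        "energy": call.energy_ok,
                    }[site.failed_criterion]
                    assert not flag and not call.is_candidate

    def test_reads_bit_reproducible(self):
        sc = build_scenario(SMALL, seed=4)
        libs1, cond1 = sim_clash_reads(sc)
        libs2, cond2 = sim_clash_reads(sc)
        assert cond1 == cond2
        assert libs1 == libs2

    def test_pcr_duplicates_collapse_to_molecules(self):
        sc = build_scenario(SMALL, seed=5)
        libs, _ = sim_clash_reads(sc)
        reads = libs["control_1"]
        clean, report = preprocess_reads(reads, SMALL.adapter3)
        # every raw read was trimmed and no molecule lost to the length filter
        assert report.adapter_trimmed == report.reads_in == len(reads)
        # duplicates exist and collapse: molecules < raw reads
        assert len(clean) < len(reads)
        assert sum(r.copies for r in clean) == len(reads)

    def test_planted_enrichment_median_near_truth(self):
        """Across replicate simulations the realized KO/control RPM
        enrichment of planted trigger sites has median within 30% of the
        planted value (drawn without the recoverability filter)."""
        cfg = SimConfig(
            n_mirnas=25, n_transcripts=60, reads_per_library=12_000,
            n_generic_sites=20, n_background_fragments=60,
            verify_recoverable=False,
        )
        folds = []
        for seed in range(12):
            sc = build_scenario(cfg, seed=seed)
            from tdmdscreen.synthetic import _draw_planted_counts

            counts = _draw_planted_counts(sc, np.random.default_rng(seed))
            for t in sc.truth.triggers:
                ctrl, ko = counts[(t.mirna_id, t.transcript_id)]
                folds.append((ko.sum() + 0.5) / (ctrl.sum() + 0.5))
        med = float(np.median(folds))
        assert 0.7 * SMALL.trigger_enrichment <= med <= 1.3 * SMALL.trigger_enrichment


class TestSmallRna:
    def test_trigger_mirna_modified_less_after_ko(self):
        mirnas = gen_mirnome(6, seed=9)
        trig = {mirnas[0].id}
        full = len(mirnas[0].sequence)

        def modified_fraction(condition, seed):
            reads = sim_smallrna_reads(mirnas, trig, condition, seed, base_mean=400.0)
            clean, _ = preprocess_reads(reads, "AGATCGGAAGAGCACACGTCTG")
            prefix = mirnas[0].sequence[:18]
            ours = [r for r in clean if r.insert[:18] == prefix]
            return sum(len(r.insert) != full for r in ours) / len(ours)

        assert modified_fraction("control", 3) > modified_fraction("ko", 3)

    def test_ko_elevates_trigger_mirna(self):
        mirnas = gen_mirnome(6, seed=9)
        trig = {mirnas[0].id}
        ctrl = sim_smallrna_reads(mirnas, trig, "control", 4)
        ko = sim_smallrna_reads(mirnas, trig, "ko", 4)
        p = mirnas[0].sequence[:18]
        n_ctrl = sum(r[4:22] == p for r in ctrl)
        n_ko = sum(r[4:22] == p for r in ko)
        assert n_ko > 3 * n_ctrl


class TestCountSims:
    def test_mirna_matrix_deterministic(self):
        ids = [f"m{i}" for i in range(10)]
        a = sim_mirna_count_matrix(ids, {"m0": 4.0}, seed=2)
        b = sim_mirna_count_matrix(ids, {"m0": 4.0}, seed=2)
        assert a.df.equals(b.df) and a.condition_of == b.condition_of

    def test_mrna_targets_shifted_down(self):
        genes = [f"g{i}" for i in range(400)]
        targets = set(genes[:100])
        cm = sim_mrna_counts(genes, targets, delta=0.5, seed=6)
        from tdmdscreen.quant import differential

        res = differential(cm, kind="mrna")
        t_med = res.loc[list(targets), "log2fc"].median()
        nt_med = res.loc[[g for g in genes if g not in targets], "log2fc"].median()
        assert t_med < nt_med - 0.25
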
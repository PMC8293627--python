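import dataclasses

import numpy as np
import pytest

import ighrep as ig
from ighrep.simulate import GenotypePreset, render_molecule, revcomp

from conftest import as_tuples, vdj_only


class TestPresets:
    def test_bundled_presets_validate(self, model):
        for name in ig.simulate.PRESET_NAMES:
            ig.preset(name, model).validate()

    def test_bad_frequency_vector_rejected(self, wt_preset):
        bad = dataclasses.replace(wt_preset, vh_freq=wt_preset.vh_freq * 2)
        with pytest.raises(ValueError):
            bad.validate()

    def test_negative_ratio_rejected(self, wt_preset):
        bad = dataclasses.replace(wt_preset, dj_to_vdj_ratio=-1.0)
        with pytest.raises(ValueError):
            bad.validate()

    def test_yaml_round_trip(self, wt_preset, tmp_path):
        path = tmp_path / "preset.yaml"
        wt_preset.to_yaml(path)
        loaded = GenotypePreset.from_yaml(path)
        assert loaded.name == wt_preset.name
        np.testing.assert_allclose(loaded.vh_freq, wt_preset.vh_freq)
        assert loaded.dj_to_vdj_ratio == wt_preset.dj_to_vdj_ratio

    def test_active_set_sizes(self):
        assert len(ig.active_vh_positions("WT_BM")) == 128
        assert len(ig.active_vh_positions("IL7RaKO_BM")) == 84
        wt = set(ig.active_vh_positions("WT_BM"))
        ko = set(ig.active_vh_positions("IL7RaKO_BM"))
        assert len(ko - wt) == 3   # all but three knockout genes sit in the WT set


class TestSampling:
    def test_zero_ratio_yields_only_vdj(self, model, wt_preset):
        rng = np.random.default_rng(0)
        events = ig.sample_events(vdj_only(wt_preset), model, 500, rng)
        assert all(e.event_class == "VDJ" for e in events)
        assert all(e.v_id is not None and e.n_vd is not None for e in events)

    def test_one_hot_vh_uses_single_gene(self, model, wt_preset):
        one_hot = np.zeros(len(model.vh))
        one_hot[6] = 1.0
        pset = dataclasses.replace(vdj_only(wt_preset), vh_freq=one_hot)
        rng = np.random.default_rng(1)
        events = ig.sample_events(pset, model, 200, rng)
        assert {e.v_id for e in events} == {model.vh[6].id}

    def test_fl_mixture_ratio(self, model, fl_preset):
        # empirical DJ fraction within 4 binomial sigma of 12/13
        rng = np.random.default_rng(2)
        n = 100_000
        events = ig.sample_events(fl_preset, model, n, rng)
        p = 12.0 / 13.0
        frac = sum(e.event_class == "DJ" for e in events) / n
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_usage_converges_to_preset(self, model, ko_preset):
        # Kolmogorov distance between empirical and preset V usage at n=1e5
        rng = np.random.default_rng(3)
        events = ig.sample_events(vdj_only(ko_preset), model, 100_000, rng)
        ids = model.vh_ids()
        counts = np.zeros(len(ids))
        pos = {g: i for i, g in enumerate(ids)}
        for e in events:
            counts[pos[e.v_id]] += 1
        emp = counts / counts.sum()
        kolmogorov = np.max(np.abs(np.cumsum(emp) - np.cumsum(ko_preset.vh_freq)))
        assert kolmogorov < 0.01

    def test_insert_incidence_matches_preset(self, model, ko_preset):
        rng = np.random.default_rng(4)
        events = ig.sample_events(vdj_only(ko_preset), model, 20_000, rng)
        ge1 = np.mean([len(e.n_vd) >= 1 for e in events])
        assert abs(ge1 - (1 - ko_preset.p_no_insert_vd)) < 0.02

    def test_trims_within_bounds(self, model, wt_preset):
        rng = np.random.default_rng(5)
        for e in ig.sample_events(wt_preset, model, 2000, rng):
            assert 0 <= e.v3 <= wt_preset.trim_max
            assert e.d5 + e.d3 < model[e.d_id].length
            assert e.j5 <= wt_preset.trim_max
            assert len(e.umi) == 6 and not set(e.umi) - set("ACGT")


class TestRendering:
    def test_identity_case(self, model, wt_preset):
        rng = np.random.default_rng(6)
        e = ig.sample_event(vdj_only(wt_preset), model, rng)
        e = dataclasses.replace(e, v3=0, d5=0, d3=0, j5=0, n_vd="", n_dj="")
        mol = render_molecule(e, model)
        assert mol == (model[e.v_id].sequence + model[e.d_id].sequence
                       + model[e.j_id].sequence)

    def test_length_identity(self, model, fl_preset):
        rng = np.random.default_rng(7)
        for e in ig.sample_events(fl_preset, model, 500, rng):
            mol = render_molecule(e, model)
            expect = (model[e.d_id].length - e.d5 - e.d3 + len(e.n_dj)
                      + model[e.j_id].length - e.j5)
            if e.event_class == "VDJ":
                expect += model[e.v_id].length - e.v3 + len(e.n_vd)
            assert len(mol) == expect

    def test_illegal_trim_raises(self, model, wt_preset):
        rng = np.random.default_rng(8)
        e = ig.sample_event(wt_preset, model, rng)
        bad = dataclasses.replace(e, d5=999)
        with pytest.raises(ValueError):
            render_molecule(bad, model)


class TestEmission:
    def test_no_duplication_no_error(self, model, wt_preset):
        rng = np.random.default_rng(9)
        pset = dataclasses.replace(wt_preset, pcr_copies_mean=1.0)
        events = ig.sample_events(pset, model, 300, rng)
        lib = ig.emit_library(events, model, seq_err=0.0, rng=rng)
        assert len(lib.read_pairs) == len(events)
        assert lib.truth_reads["molecule_id"].nunique() == len(events)

    def test_error_free_read2_is_template_substring(self, model, wt_preset):
        rng = np.random.default_rng(10)
        events = ig.sample_events(wt_preset, model, 200, rng)
        lib = ig.emit_library(events, model, seq_err=0.0, rng=rng)
        by_id = {e.molecule_id: e for e in events}
        for rp in lib.read_pairs[:50]:
            e = by_id[rp.read_id.rsplit(".", 1)[0]]
            mol = render_molecule(e, model)
            assert revcomp(rp.r2) in (ig.locus.synthetic_flank(model.build_tag,
                                      e.v_id or e.d_id) + mol)

    def test_duplication_mean(self, model, wt_preset):
        rng = np.random.default_rng(11)
        events = ig.sample_events(wt_preset, model, 1000, rng)
        lib = ig.emit_library(events, model, seq_err=0.0, rng=rng)
        ratio = len(lib.read_pairs) / len(events)
        # copies = 1 + Poisson(2): sd of the mean ~ sqrt(2/1000)
        assert abs(ratio - 3.0) < 4 * np.sqrt(2.0 / 1000)

    def test_seed_determinism(self, model, fl_preset, tmp_path):
        outs = []
        for rep in range(2):
            rng = np.random.default_rng(42)
            events = ig.sample_events(fl_preset, model, 100, rng)
            lib = ig.emit_library(events, model, seq_err=0.01, rng=rng)
            f1, f2 = tmp_path / f"r1_{rep}.fastq", tmp_path / f"r2_{rep}.fastq"
            lib.write_fastq(f1, f2)
            outs.append((f1.read_bytes(), f2.read_bytes(),
                         lib.truth_events.to_csv()))
        assert outs[0] == outs[1]

    def test_short_read_len_rejected(self, model, wt_preset):
        rng = np.random.default_rng(12)
        events = ig.sample_events(wt_preset, model, 10, rng)
        with pytest.raises(ValueError):
            ig.emit_library(events, model, seq_err=0.0, rng=rng, read_len=40)

    def test_empty_events_rejected(self, model):
        with pytest.raises(ValueError):
            ig.emit_library([], model, seq_err=0.0, rng=np.random.default_rng(0))

    def test_truth_table_links_reads(self, small_library):
        events, lib = small_library
        assert lib.truth_reads["read_id"].is_unique
        assert set(lib.truth_reads["molecule_id"]) == {e.molecule_id for e in events}
        assert len(lib.truth_reads) == len(lib.read_pairs)
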
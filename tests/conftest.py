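import dataclasses

import numpy as np
import pytest

import ighrep as ig
from ighrep.assign import SegmentIndex


@pytest.fixture(scope="session")
def model():
    return ig.default_locus()


@pytest.fixture(scope="session")
def seg_index(model):
    return SegmentIndex(model)


@pytest.fixture(scope="session")
def wt_preset(model):
    return ig.preset("WT_BM", model)


@pytest.fixture(scope="session")
def ko_preset(model):
    return ig.preset("IL7RaKO_BM", model)


@pytest.fixture(scope="session")
def fl_preset(model):
    return ig.preset("FL", model)


def vdj_only(preset):
    """A preset restricted to fully recombined (VDJ) molecules."""
    return dataclasses.replace(preset, dj_to_vdj_ratio=0.0)


@pytest.fixture(scope="session")
def small_library(model, wt_preset):
    """1,000-molecule WT library with realistic duplication and error rate."""
    rng = np.random.default_rng(101)
    events = ig.sample_events(wt_preset, model, 1000, rng)
    lib = ig.emit_library(events, model, seq_err=0.001, rng=rng)
    return events, lib


def as_tuples(lib):
    return [(p.read_id, p.r1, p.q1, p.r2, p.q2) for p in lib.read_pairs]
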
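import logging

import numpy as np
import pytest

from pmdarith import encoding, synth

logging.getLogger("pmdarith").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_like_small():
    """Reduced study-like dataset shared across read-only tests."""
    return synth.make_fixture_dataset("paper_like", seed=11, n_cells=160)


@pytest.fixture(scope="session")
def paper_like_encoding(paper_like_small):
    ds = paper_like_small
    reg = encoding.binwise_regression(ds.pop)
    hist = encoding.build_coding_history(reg)
    candidates = hist.per_period[:, list(hist.periods).index("preop"),
                                 list(hist.factors).index("arithmetic")]
    ireg = encoding.regress_instruction(ds.instructed_pop)
    selective, unevaluable = encoding.instructed_task_filter(candidates, ireg)
    return {"reg": reg, "hist": hist, "candidates": candidates,
            "selective": selective, "unevaluable": unevaluable}


@pytest.fixture(scope="session")
def null_small():
    """No planted effects: 200 cells over the 160 balanced trials."""
    return synth.make_fixture_dataset("null", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
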
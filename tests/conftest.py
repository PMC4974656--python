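import numpy as np
import pytest

from saltpepper.stimulus import (
    ScreenGeometry,
    build_design,
    generate_sequence,
)


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def short_design():
    """A 5-minute Hartley session design, shared by fitting unit tests."""
    seq = generate_sequence(300.0, seed=123)
    return build_design(seq)


@pytest.fixture(scope="session")
def full_design():
    """The standard 20-minute session design."""
    seq = generate_sequence(1200.0, seed=321)
    return build_design(seq)


@pytest.fixture(scope="session")
def fitted_field():
    """One 50-cell, 20-minute synthetic field run through the whole chain.

    Generation, preprocessing (neuropil correction + deconvolution) and
    per-cell kernel fitting are expensive, so the result is shared by the
    recovery, selection and robustness-filter tests.
    """
    from saltpepper.kernel_fit import FitConfig, _CellDesign, fit_cell
    from saltpepper.preprocess import preprocess_traces
    from saltpepper.synthetic_data import SheetConfig, generate_dataset

    ds = generate_dataset(SheetConfig(n_cells=50, seed=2024), seed=2024)
    traces = ds.to_trace_set()
    preprocess_traces(traces)
    cfg = FitConfig()
    cd = _CellDesign(ds.design, ds.running, cfg.n_lags)
    fits = [fit_cell(traces.inferred_spikes[i], cd, config=cfg)
            for i in range(traces.n_cells)]
    return {"dataset": ds, "traces": traces, "fits": fits, "fit_config": cfg}

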
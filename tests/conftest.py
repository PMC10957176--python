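import pytest

from riboaccount import synthetic as syn

CHASE_TIMES = [0.0, 30.0, 60.0, 120.0, 180.0, 300.0, 600.0, 900.0]


def rta_spec(**overrides) -> syn.RtaSimSpec:
    """A run-off design resembling the cultured-cell time course."""
    kw = dict(
        t_half_s=70.0,
        stalled_frac=0.1,
        mean_signal=1000.0,
        background_mean=50.0,
        cv=0.4,
        chase_times_s=CHASE_TIMES,
        cells_per_timepoint=300,
        seed=1,
    )
    kw.update(overrides)
    return syn.RtaSimSpec(**kw)


@pytest.fixture
def rta_events():
    spec = rta_spec()
    events, truth = syn.gen_rta_events(spec)
    return events, truth, spec
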
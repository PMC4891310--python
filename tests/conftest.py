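import pytest

from coagree import MeasurementRecord, Method, PairedSample, Timepoint


def make_record(subject="S1", timepoint=Timepoint.BASELINE, method=Method.REFERENCE,
                replicate_index=1, **values):
    defaults = dict(ci=4.5, svi=30.0, svri=1400.0, svv=15.0, hr=150.0, sbp=90.0)
    defaults.update(values)
    return MeasurementRecord(subject_id=subject, timepoint=timepoint, method=method,
                             replicate_index=replicate_index, **defaults)


def make_sample(subject="S1", timepoint=Timepoint.BASELINE, ref=None, test=None, flags=()):
    """Paired sample with given per-variable dicts (defaults are shared)."""
    base = dict(ci=4.5, svi=30.0, svri=1400.0, svv=15.0, hr=150.0, sbp=90.0)
    ref_values = dict(base, **(ref or {}))
    test_values = dict(base, **(test or {}))
    return PairedSample(subject, timepoint, ref_values, test_values, frozenset(flags))


def samples_from_pairs(pairs, variable="ci", timepoint=Timepoint.BASELINE):
    """One clean sample per (ref, test) value pair of a single variable."""
    return [
        make_sample(subject=f"P{i}", timepoint=timepoint,
                    ref={variable: r}, test={variable: t})
        for i, (r, t) in enumerate(pairs)
    ]


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def sample_factory():
    return make_sample
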
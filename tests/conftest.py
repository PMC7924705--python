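import pytest

from irispipe import Circle, EyeSpec, make_cohort, render_eye

MASTER_SEED = 20260919


@pytest.fixture(scope="session")
def clean_eye():
    """One noise-free synthetic eye with concentric circles."""
    spec = EyeSpec(
        subject_id=1,
        pupil=Circle(xc=160, yc=140, r=25),
        iris=Circle(xc=160, yc=140, r=70),
        texture_seed=7,
    )
    return render_eye(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """20 subjects x 10 captures, additive noise sd 8: the benchmark cohort.

    The first five captures per subject serve as the enrollment set, the
    last five as the test set; the enrollment half doubles as the
    100-image segmentation-recovery benchmark.
    """
    truths, records = make_cohort(20, 10, MASTER_SEED, noise_sigma=8.0)
    return truths, records


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x 2 captures for cheap statistics tests."""
    truths, records = make_cohort(8, 2, MASTER_SEED + 1, noise_sigma=8.0)
    return truths, records


def circle_error(found: Circle, truth: Circle) -> float:
    return max(
        abs(found.xc - truth.xc), abs(found.yc - truth.yc), abs(found.r - truth.r)
    )
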
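import numpy as np
import pytest

from audioprofile import AudiogramRecord, generate_cohort, tbc1d24_profile_spec


@pytest.fixture
def full_record():
    """A complete binaural audiogram across all canonical frequencies."""
    return AudiogramRecord(
        subject_id="S1",
        age=42.0,
        ear="binaural",
        thresholds={125: 15, 250: 20, 500: 30, 1000: 35, 2000: 40, 4000: 55, 8000: 60},
        group="TBC",
    )


@pytest.fixture
def noiseless_cohort():
    """Noiseless cohort on the published TBC1D24 band curves (60 subjects)."""
    return generate_cohort(tbc1d24_profile_spec(noise_sd=0.0, seed=11))


def make_single_freq_records(
    rng: np.random.Generator,
    n: int,
    slope: float,
    frequency: int = 2000,
    noise_sd: float = 5.0,
    age_range: tuple[float, float] = (10.0, 60.0),
    baseline: float = 0.0,
    anchor_age: float = 0.0,
    group: str = "unknown",
    prefix: str = "R",
) -> list[AudiogramRecord]:
    """Cross-sectional records at one frequency with
    threshold = baseline + slope*(age - anchor_age) + noise.

    ``baseline``/``anchor_age`` let groups share a common hearing level at a
    reference age while deteriorating at group-specific rates.
    """
    ages = rng.uniform(*age_range, size=n)
    noise = rng.normal(0.0, noise_sd, size=n)
    return [
        AudiogramRecord(
            subject_id=f"{prefix}{i}",
            age=float(a),
            ear="binaural",
            thresholds={
                frequency: float(np.clip(baseline + slope * (a - anchor_age) + e, -10, 120))
            },
            group=group,
        )
        for i, (a, e) in enumerate(zip(ages, noise))
    ]
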
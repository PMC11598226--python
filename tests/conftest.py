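import pytest

from somnoposture import Geometry, Scenario, Segment


@pytest.fixture(scope="session")
def geometry() -> Geometry:
    return Geometry()


@pytest.fixture()
def single_segment_scenario():
    """10 s of noise-free left lateral posture at the default period."""

    def make(label: str = "LLP", duration: float = 10.0, noise_sd: float = 0.0,
             seed: int = 0) -> Scenario:
        return Scenario(
            schedule=(Segment(label=label, start=0.0, end=duration),),
            noise_sd=noise_sd,
            seed=seed,
        )

    return make
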
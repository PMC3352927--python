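import logging

import pytest

from zfscreen.cardio_analysis import CardioThresholds, calibrate_arrest_threshold

# silence per-well warnings in pipeline tests
logging.getLogger("zfscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def thresholds() -> CardioThresholds:
    """Default decision thresholds (arrest amplitude calibrated once)."""
    return CardioThresholds(arrest_of_amplitude=calibrate_arrest_threshold(2.0))
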
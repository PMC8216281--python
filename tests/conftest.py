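import numpy as np
import pytest
from hypothesis import settings

from conascreen import detect, synthgen

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STANDARD_SEED = 42


@pytest.fixture(scope="session")
def channels():
    """Default FITC (RNA) / mCherry (protein) channel pair."""
    return synthgen.default_channels()


@pytest.fixture(scope="session")
def standard_scene(channels):
    """The standard 20-bead synthetic field (default noise, SNR >~ 25)."""
    spec = synthgen.SceneSpec()
    stack, truth = synthgen.generate_scene(spec, channels, seed=STANDARD_SEED)
    return spec, stack, truth


@pytest.fixture(scope="session")
def standard_loci(standard_scene):
    _, stack, _ = standard_scene
    return detect.detect_beads(stack["FITC"], detect.DetectParams())


def match_to_truth(locus, truth, max_dist=5.0):
    """Nearest ground-truth bead within ``max_dist`` pixels, or None."""
    dists = [
        np.hypot(locus.center_row - b.center_row,
                 locus.center_col - b.center_col)
        for b in truth
    ]
    j = int(np.argmin(dists))
    return truth[j] if dists[j] <= max_dist else None
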
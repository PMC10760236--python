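import numpy as np
import pytest
from shapely.geometry import Polygon

from neurospot import (AnalysisConfig, DendriteBranch, NeuronGeometry,
                       SyntheticConfig)


@pytest.fixture
def square_geometry():
    """10x10-pixel square soma (pixel 107.5 nm) with one straight +x branch
    of 75 um, half-width 5 pixels."""
    ps = 107.5
    s = 10 * ps
    soma = Polygon([(0, 0), (s, 0), (s, s), (0, s)])
    branch = DendriteBranch(
        skeleton=np.array([[s, s / 2], [s + 75_000.0, s / 2]]),
        half_width=5 * ps)
    return NeuronGeometry(soma=soma, branches=[branch], pixel_size_xy=ps)


@pytest.fixture
def flat_synth_config():
    """Synthetic preset with no spatial structure beyond the mask: flat
    dendritic density, no spine/coexistence enrichment, no localisation
    error, no transcription sites."""
    return SyntheticConfig(
        n_branches=1, branch_length_um=100.0, decay_length_um=float("inf"),
        localization_error_sd_nm=0.0, n_transcription_sites=0,
        mean_soma_mrnas=0.0)


@pytest.fixture
def analysis_2d():
    return AnalysisConfig(distance_mode="2d")
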
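import numpy as np
import pytest

from pairvox.pipeline import RunConfig, compute_pair_comparisons
from pairvox.synth_calls import CallTemplate, ColonySpec, gen_colony


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_template():
    return CallTemplate(contour_points=((0.0, 3000.0), (1.0, 3000.0)),
                        duration_s=0.2, n_harmonics=1, snr_db=np.inf)


@pytest.fixture(scope="session")
def small_colony():
    """A 4-pair colony with perfect imitation, scored once per session."""
    colony = gen_colony(ColonySpec(n_pairs=4, imitation_distortion=0.0,
                                   rng_seed=11))
    cfg = RunConfig(exemplars_per_type=3, seed=11)
    scores, mcv = compute_pair_comparisons(
        colony.annotations, colony.pairs,
        lambda cid: colony.waveforms[cid], cfg)
    return colony, scores, mcv


def brute_force_xcorr(a, b, max_lag=None, min_overlap_frac=0.5):
    """Independent per-lag loop oracle for the spectrogram correlation:
    slices the overlap explicitly and uses np.corrcoef."""
    am, bm = a.magnitudes, b.magnitudes
    ta, tb = am.shape[1], bm.shape[1]
    shorter = min(ta, tb)
    if max_lag is None:
        max_lag = shorter
    min_overlap = max(1, int(np.ceil(min_overlap_frac * shorter)))
    best = (-np.inf, None, None)
    for lag in sorted(range(-(tb - 1), ta), key=lambda l: (abs(l), l)):
        if abs(lag) > max_lag:
            continue
        lo_a, hi_a = max(0, lag), min(ta, tb + lag)
        if hi_a - lo_a < min_overlap:
            continue
        x = am[:, lo_a:hi_a].ravel()
        y = bm[:, lo_a - lag:hi_a - lag].ravel()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best[0] + 1e-12:
            best = (r, lag, hi_a - lo_a)
    return best
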
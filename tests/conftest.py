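import numpy as np
import pytest

from flimfret.binding import BinnedPoint
from flimfret.synthgen import hill_efficiency


def hill_bins(emax, kd, h, mids):
    """Noiseless binned points lying exactly on a Hill curve."""
    return [
        BinnedPoint(ratio_low=m - 0.05, ratio_high=m + 0.05, ratio_mid=m,
                    mean_e=float(hill_efficiency(m, emax, kd, h)), sem_e=1.0, n_roi=100)
        for m in mids
    ]


@pytest.fixture
def noiseless_hill_bins():
    mids = np.array([0.05, 0.15, 0.3, 0.5, 0.8, 1.2, 1.8, 2.5])
    return hill_bins(40.0, 0.3, 1.5, mids)


@pytest.fixture(scope="session")
def roi_dataset():
    """A paper-scale synthetic binding dataset with known truth."""
    from flimfret.synthgen import SynthBindingParams, gen_roi_dataset

    params = SynthBindingParams(emax=40.0, kd=0.3, h=1.0, n_roi=3000, seed=42)
    df, truth = gen_roi_dataset(params, condition_label="ref")
    return params, df, truth
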
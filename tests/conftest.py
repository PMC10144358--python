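import numpy as np
import pytest

import medoidspec as ms
from medoidspec import synthetic as syn
from medoidspec.trajectory import AtomSelection


@pytest.fixture(scope="session")
def dimer_run():
    """Standard 500-frame planted-cluster dimer with features and labels."""
    spec = syn.DimerGeneratorSpec(seed=3)
    traj, labels = syn.make_dimer_trajectory(spec)
    feat = ms.PlanePairFeaturizer(
        sel_a=AtomSelection("donor", syn.DIMER_DONOR_INDICES),
        sel_b=AtomSelection("acceptor", syn.DIMER_ACCEPTOR_INDICES),
        local_frame_atoms=syn.DIMER_LOCAL_FRAME,
    )
    raw = feat.fit(traj).transform(traj)
    std, params = ms.standardize(raw.select_dtypes("number"))
    return {"traj": traj, "labels": labels, "raw": raw, "std": std, "params": params}


@pytest.fixture(scope="session")
def small_dimer():
    """A fast 60-frame, 3-cluster dimer for cheap integration checks."""
    spec = syn.DimerGeneratorSpec(n_frames=60, n_clusters=3, seed=11)
    traj, labels = syn.make_dimer_trajectory(spec)
    feat = ms.PlanePairFeaturizer(
        sel_a=AtomSelection("donor", syn.DIMER_DONOR_INDICES),
        sel_b=AtomSelection("acceptor", syn.DIMER_ACCEPTOR_INDICES),
        local_frame_atoms=syn.DIMER_LOCAL_FRAME,
    )
    raw = feat.fit(traj).transform(traj)
    std, _ = ms.standardize(raw.select_dtypes("number"))
    return {"traj": traj, "labels": labels, "std": std}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
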
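import numpy as np
import pandas as pd
import pytest

from matodd import stimuli as st


@pytest.fixture(scope="session")
def scene_obj2():
    return st.SceneSpec(st.OBJECTS[2], 1, 0)


@pytest.fixture(scope="session")
def white_ill1():
    return st.white_point(1)


@pytest.fixture(scope="session")
def gc_image(scene_obj2):
    return st.render_object(scene_obj2, st.MaterialSpec("GC", 0.06), 128)


def make_planted_dataset(
    n=75, p=96, planted=(3, 17, 40, 55, 80), snr=5.0, seed=0, n_tasks=6
):
    """Linear model with a sparse planted signal among p features.

    Returns a RegressionDataset whose response depends on ``planted``
    columns only, with noise scaled so that signal SD / noise SD = snr.
    """
    from matodd.regression import assemble_dataset

    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
    )
    w = np.zeros(p)
    w[list(planted)] = rng.uniform(1.0, 2.5, size=len(planted)) * rng.choice(
        [-1, 1], size=len(planted)
    )
    signal = X.to_numpy() @ w
    noise_sd = signal.std() / snr
    y = pd.Series(signal + noise_sd * rng.normal(size=n))
    tasks = pd.Series(
        np.array([f"task{i % n_tasks}" for i in range(n)])
    )
    idx = [f"c{i}" for i in range(n)]
    X.index = y.index = tasks.index = idx
    return assemble_dataset(X, y, tasks), [f"f{j}" for j in planted]
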
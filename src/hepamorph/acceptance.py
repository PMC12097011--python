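"""Reference experiments recomputing the package's headline quantities.

These are the desk-scale study conditions behind the reproducibility
checks: fully synthetic, seeded, and executed through the public API.
"""

from __future__ import annotations

import numpy as np

from . import phantom as ph
from . import steatosis as st

__all__ = ["classifier_holdout_accuracy", "separable_phantom_config"]


def separable_phantom_config(seed: int, shape=(128, 128, 128)) -> ph.PhantomConfig:
    """A steatosis-vs-parenchyma phantom for classifier evaluation.

    Large smooth steatotic regions (big droplets) around a minimal
    central-vein stub, no sinusoid mesh; the steatosis/parenchyma
    intensity separation is 70 gray levels at noise sd 8, i.e. 8.75
    noise standard deviations — comfortably separable.
    """
    return ph.PhantomConfig(
        shape=tuple(shape),
        seed=seed,
        tree_params=ph.TreeParams(root_radius=8.0, depth=0, root_length_frac=0.2),
        sinusoid_params=ph.SinusoidParams(node_density=0.0),
        steatosis_params=ph.SteatosisParams(droplet_radius=(12.0, 20.0)),
        intensity_model=ph.IntensityModel(noise_sd=8.0, bias_amplitude=0.0,
                                          stripe_amplitude=0.0),
    )


def _annotate(truth: ph.PhantomTruth, fraction: float, rng: np.random.Generator):
    """Sparse brush-style annotations: a fraction of each tissue class."""
    lab = np.asarray(truth.labels.data)
    ann = np.zeros(lab.shape, np.int8)
    for code, sel in ((st.TARGET, lab == 6), (st.BACKGROUND, lab == 0)):
        idx = np.flatnonzero(sel.ravel())
        take = rng.choice(idx, size=max(1, int(len(idx) * fraction)), replace=False)
        ann.ravel()[take] = code
    return ann


def classifier_holdout_accuracy(
    seed: int,
    shape=(128, 128, 128),
    annotate_fraction: float = 0.05,
    iterations: int = 600,
    scales_um=(1.0, 3.0),
) -> dict:
    """Train on one phantom, evaluate on held-out annotations of a second.

    Returns the validation voxel accuracy (percent) on the annotated
    voxels of an independently seeded phantom, plus the number of
    evaluation voxels and the intensity separation in noise-sd units.
    """
    cfg_train = separable_phantom_config(seed, shape)
    cfg_eval = separable_phantom_config(seed + 1, shape)

    truth_tr, gray_tr = ph.generate_phantom(cfg_train)
    feats_tr = st.extract_features(gray_tr, scales_um)
    ann_tr = _annotate(truth_tr, annotate_fraction, np.random.default_rng(seed))
    clf, curves = st.train(
        feats_tr, gray_tr.with_data(ann_tr, kind="labels"),
        iterations=iterations, seed=seed, scales_um=tuple(scales_um),
    )

    truth_ev, gray_ev = ph.generate_phantom(cfg_eval)
    feats_ev = st.extract_features(gray_ev, scales_um)
    ann_ev = _annotate(truth_ev, annotate_fraction, np.random.default_rng(seed + 1))
    sel = ann_ev != st.UNLABELED
    scores = clf.scores(feats_ev[sel])
    pred = scores >= clf.decision_threshold
    y = ann_ev[sel] == st.TARGET
    accuracy = float((pred == y).mean())

    im = cfg_train.intensity_model
    separation_sd = abs(im.steatosis_mean - im.parenchyma_mean) / im.noise_sd
    return {
        "accuracy_percent": 100.0 * accuracy,
        "n_eval_voxels": int(sel.sum()),
        "separation_sd": separation_sd,
        "final_train_val_accuracy": curves.final_val_accuracy,
    }
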
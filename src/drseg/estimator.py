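"""Scikit-learn-style estimator wrapping the train/segment pipeline.

``DomainRandomizedSegmenter`` is a thin orchestration layer: ``fit`` consumes
a corpus of label maps (no images) and trains the segmentation network on the
synthetic stream; ``predict`` runs the full test-time pipeline on intensity
volumes. It follows the sklearn conventions (constructor stores parameters
verbatim, fitted state carries a trailing underscore, ``get_params`` /
``set_params`` work for model selection), so it composes with sklearn
tooling where that is meaningful for 3D volumes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import GenerationConfig
from .generator import sample_training_pair
from .inference import predict_flip_augmented, postprocess, preprocess
from .nn import ModelConfig
from .training import desk_learning_rate, retain_model, train
from .volumes import IntensityVolume, LabelVolume, LateralPairs

__all__ = ["DomainRandomizedSegmenter"]


class DomainRandomizedSegmenter(BaseEstimator):
    """Segmenter trained purely on synthetic images generated from label maps.

    Parameters
    ----------
    gen_config : GenerationConfig or None
        Priors of the generative model; must carry the label bookkeeping
        (generation/segmentation/extracerebral labels, lateral pairs).
    model_config : ModelConfig or None
        Network architecture; defaults to the reduced 3-level / 8-feature net.
    n_steps : int
        Number of single-sample Adam updates.
    learning_rate : float or callable step -> float
        Adam step size; defaults to the desk step-decay schedule.
    checkpoint_every : int
        Snapshot period; the retained model is the tail average of the last
        checkpoints unless validation vetoes it (see ``retain_model``).
    n_validation : int
        Held-out synthetic pairs used for the retention decision.
    flip_augment : bool
        Average predictions of the scan and its left/right mirror at test time.
    random_state : int
        Seed for generation, initialisation, and training order.
    """

    def __init__(self, gen_config=None, model_config=None, n_steps=4500,
                 learning_rate=desk_learning_rate, checkpoint_every=500,
                 n_validation=12, flip_augment=True, random_state=0):
        self.gen_config = gen_config
        self.model_config = model_config
        self.n_steps = n_steps
        self.learning_rate = learning_rate
        self.checkpoint_every = checkpoint_every
        self.n_validation = n_validation
        self.flip_augment = flip_augment
        self.random_state = random_state

    def fit(self, X, y=None, lesion_masks=None):
        """Train on a corpus of :class:`LabelVolume` (``y`` is unused)."""
        if not X:
            raise ValueError("the corpus is empty")
        if not all(isinstance(v, LabelVolume) for v in X):
            raise TypeError("fit expects a list of LabelVolume")
        gen_config = self.gen_config if self.gen_config is not None else GenerationConfig()
        model_config = self.model_config if self.model_config is not None else ModelConfig()
        rng = np.random.default_rng(self.random_state)
        checkpoints, log = train(
            list(X), gen_config, model_config, self.n_steps, self.checkpoint_every,
            rng, learning_rate=self.learning_rate, lesion_masks=lesion_masks,
        )
        val_rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 1]))
        validation = [
            sample_training_pair(list(X), gen_config, val_rng, lesion_masks=lesion_masks)
            for _ in range(max(1, self.n_validation))
        ]
        self.checkpoint_ = retain_model(checkpoints, validation)
        self.model_ = self.checkpoint_.build()
        self.training_log_ = log
        self.gen_config_ = gen_config
        self.pairs_ = LateralPairs(list(gen_config.lateral_pairs))
        return self

    def predict(self, X):
        """Segment one volume or a list of volumes at isotropic r_hr."""
        single = isinstance(X, IntensityVolume)
        scans = [X] if single else list(X)
        out = []
        for scan in scans:
            pre = preprocess(scan, r_hr=self.gen_config_.r_hr)
            soft = self.predict_proba_volume(pre)
            seg = postprocess(soft, self.checkpoint_.segmentation_labels,
                              spacing=pre.spacing)
            seg.affine = pre.affine.copy()
            out.append(seg)
        return out[0] if single else out

    def predict_proba_volume(self, scan: IntensityVolume) -> np.ndarray:
        """Soft prediction on an already-preprocessed volume."""
        self._check_fitted()
        return predict_flip_augmented(
            self.checkpoint_, scan, self.pairs_,
            lr_axis=self.gen_config_.lr_axis, flip_augment=self.flip_augment,
        )

    def score(self, X, y):
        """Mean foreground Dice of predictions against reference label maps."""
        from .evaluation import hard_dice

        preds = self.predict(X) if not isinstance(X, IntensityVolume) else [self.predict(X)]
        refs = y if isinstance(y, (list, tuple)) else [y]
        scores = []
        for pred, ref in zip(preds, refs):
            for lab in self.checkpoint_.segmentation_labels:
                scores.append(hard_dice(pred, ref, lab))
        return float(np.mean(scores))

    def _check_fitted(self):
        if not hasattr(self, "checkpoint_"):
            raise RuntimeError("this DomainRandomizedSegmenter is not fitted yet")
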
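"""The desk-scale reference study: fixed problem sizes and configurations
for running the full pipeline on one CPU.

Everything here is a frozen study condition, shared by the validation suite
and the reproduction script so both exercise the identical pipeline:

* phantoms at 32x32x32 voxels, four simulated protocols;
* cohorts of 48 scans (24 with, 24 without WM abnormality), split 24 train /
  8 validation / 16 test, class-balanced in every partition;
* the small CNN preset (two conv blocks of 8/16 filters, 32 dense units)
  trained 30 epochs with Adam at 3e-3;
* permutation retrains shortened to 8 epochs — a label-shuffled model sits
  at chance regardless of training length, so the null is unaffected while
  fifty retrains stay affordable on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .clustering import RFCMParams
from .cnn import CNNConfig, TrainingConfig
from .evaluation import PermutationResult, permutation_test
from .io import ScanManifest, Volume, rng_from
from .phantom import (PhantomSample, TissueTemplate, easy_protocols,
                      generate_cohort, generate_template)
from .pipeline import build_reference, make_pipeline_factory, prepare_inputs

SHAPE = (32, 32, 32)
N_PROTOCOLS = 4
N_PER_CLASS = 24                       # 48 scans total
TRAIN_PER_CLASS, VAL_PER_CLASS, TEST_PER_CLASS = 12, 4, 8
OBSERVED_EPOCHS = 30
PERMUTATION_EPOCHS = 8
LEARNING_RATE = 3e-3


def desk_cnn_config() -> CNNConfig:
    return CNNConfig.desk_scale(SHAPE)


def desk_training_config(seed: int = 0, max_epochs: int = OBSERVED_EPOCHS) -> TrainingConfig:
    return TrainingConfig(learning_rate=LEARNING_RATE, batch_size=4,
                          max_epochs=max_epochs, seed=seed)


@dataclasses.dataclass
class DeskStudy:
    """A fully prepared desk-scale cohort: clustered inputs plus the fixed
    balanced train/val/test split."""

    template: TissueTemplate
    reference: Volume
    samples: list[PhantomSample]
    manifest: ScanManifest
    x: np.ndarray                      # (N, D, H, W) thresholded clusters
    y: np.ndarray                      # (N,) 1 = WM abnormality present
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def split(self):
        return ((self.x[self.train_idx], self.y[self.train_idx]),
                (self.x[self.val_idx], self.y[self.val_idx]),
                (self.x[self.test_idx], self.y[self.test_idx]))


def prepare_study(seed: int, n_per_class: int = N_PER_CLASS,
                  params: RFCMParams | None = None) -> DeskStudy:
    """Generate the easy cohort, cluster every scan, and fix the balanced
    split. Deterministic given ``seed``."""
    template = generate_template(SHAPE, seed=rng_from(seed, "template").integers(2**31))
    protocols = easy_protocols(N_PROTOCOLS)
    reference = build_reference(template, protocols[0],
                                seed=rng_from(seed, "reference").integers(2**31))
    samples, manifest = generate_cohort(template, protocols, n_per_class,
                                        n_per_class,
                                        seed=rng_from(seed, "cohort").integers(2**31))
    x, y, _ = prepare_inputs(samples, template, reference, params=params)
    rng = rng_from(seed, "split")
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    n_tr, n_va = TRAIN_PER_CLASS, VAL_PER_CLASS
    scale = n_per_class / N_PER_CLASS
    n_tr, n_va = int(round(n_tr * scale)), max(int(round(n_va * scale)), 1)
    train_idx = np.concatenate([pos[:n_tr], neg[:n_tr]])
    val_idx = np.concatenate([pos[n_tr:n_tr + n_va], neg[n_tr:n_tr + n_va]])
    test_idx = np.concatenate([pos[n_tr + n_va:], neg[n_tr + n_va:]])
    return DeskStudy(template=template, reference=reference, samples=samples,
                     manifest=manifest, x=x, y=y, train_idx=train_idx,
                     val_idx=val_idx, test_idx=test_idx)


def run_permutation_study(study: DeskStudy, seed: int,
                          n_permutations: int = 50,
                          observed_epochs: int = OBSERVED_EPOCHS,
                          permutation_epochs: int = PERMUTATION_EPOCHS,
                          ) -> PermutationResult:
    """Train the observed model and build the label-shuffled null."""
    train_set, val_set, test_set = study.split()
    observed_factory = make_pipeline_factory(
        desk_cnn_config(), desk_training_config(max_epochs=observed_epochs))
    pipe = observed_factory(rng_from(seed, "observed-model").integers(2**31))
    pipe.fit(*train_set, *val_set)
    observed = pipe.score_accuracy(*test_set)
    null_factory = make_pipeline_factory(
        desk_cnn_config(), desk_training_config(max_epochs=permutation_epochs))
    return permutation_test(null_factory, train_set, val_set, test_set,
                            n_permutations=n_permutations, seed=seed,
                            observed_accuracy=observed)
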
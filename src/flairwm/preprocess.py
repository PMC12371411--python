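"""Quality-control filters and in-scope preprocessing computations.

Bias-field correction (N4) and nonlinear registration to the template are
external steps performed by user-installed tools; this module only exposes
shell-out hooks for them. Everything the pipeline computes itself — the
minimum-dimension filter, the 2D/3D slice-count rules, white-matter
extraction, and the mutual-information registration QC — lives here. QC
decisions are pure functions of the image shape.
"""

from __future__ import annotations

import dataclasses
import shlex
import subprocess
import warnings

import numpy as np

from .io import Volume

#: Minimum voxel counts along the three canonical axes for an eligible scan.
DEFAULT_MIN_DIMS = (128, 192, 22)
#: Scans with this many slices or fewer count as 2D acquisitions.
SLICES_2D_MAX = 70
#: Strict 3D eligibility (protocol-generalization experiments) needs at least
#: this many slices.
SLICES_3D_STRICT_MIN = 192


@dataclasses.dataclass
class QCReport:
    scan_id: str
    passes_min_dims: bool
    dimensionality: str              # "2D" or "3D"
    eligible_3d_strict: bool
    mi_after_registration: float | None = None


def check_min_dims(volume: Volume, mins: tuple[int, int, int] = DEFAULT_MIN_DIMS) -> bool:
    """True iff every axis meets its minimum voxel count."""
    return all(s >= m for s, m in zip(volume.shape, mins))


def classify_dimensionality(volume: Volume, threshold_2d: int = SLICES_2D_MAX,
                            threshold_3d_strict: int = SLICES_3D_STRICT_MIN,
                            scan_id: str = "", mins: tuple[int, int, int] = DEFAULT_MIN_DIMS,
                            ) -> QCReport:
    """Apply the slice-count rules along the third (slice) axis."""
    n = volume.n_slices
    return QCReport(
        scan_id=scan_id,
        passes_min_dims=check_min_dims(volume, mins),
        dimensionality="2D" if n <= threshold_2d else "3D",
        eligible_3d_strict=n >= threshold_3d_strict,
    )


def extract_wm(image: Volume, wm_prob: np.ndarray | Volume) -> Volume:
    """Extract the white-matter compartment by voxelwise multiplication with
    the template's WM probability map; non-WM tissue is suppressed toward 0."""
    prob = wm_prob.data if isinstance(wm_prob, Volume) else np.asarray(wm_prob, float)
    if prob.shape != image.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs wm_prob {prob.shape}")
    return Volume(image.data * prob, image.spacing)


def mutual_information(a: Volume, b: Volume, bins: int = 64) -> float:
    """Mutual information of the joint intensity histogram, in nats.

    Equal-width bins span each image's own [min, max]. MI(a, a) equals the
    entropy of a's histogram; constant inputs yield 0 with a warning.
    """
    x = a.data.ravel()
    y = b.data.ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("mutual_information: constant input, MI is 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


@dataclasses.dataclass
class ExternalPreprocessing:
    """Shell-out hooks for the external preprocessing tools.

    Commands are templates with ``{input}``/``{output}`` (and for
    registration ``{template}``) placeholders, e.g.
    ``"N4BiasFieldCorrection -i {input} -o {output}"``. Registration is run
    ``n_registrations`` times consecutively with identical parameters.
    """

    n4_command: str | None = None
    registration_command: str | None = None
    template_path: str | None = None
    wm_prob_path: str | None = None
    n_registrations: int = 3

    def run_n4(self, input_path: str, output_path: str) -> None:
        if not self.n4_command:
            raise RuntimeError("no n4_command configured")
        cmd = self.n4_command.format(input=input_path, output=output_path)
        subprocess.run(shlex.split(cmd), check=True)

    def run_registration(self, input_path: str, output_path: str) -> None:
        if not self.registration_command:
            raise RuntimeError("no registration_command configured")
        if not self.template_path:
            raise RuntimeError("no template_path configured")
        src = input_path
        for _ in range(self.n_registrations):
            cmd = self.registration_command.format(
                input=src, output=output_path, template=self.template_path)
            subprocess.run(shlex.split(cmd), check=True)
            src = output_path
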
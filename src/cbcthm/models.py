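"""Model/Results API over the registration and correction pipelines.

Registration is a model fit in the literal sense — transform parameters are
estimated from image data by maximizing a similarity objective — so the
top-level interface mirrors the familiar statistical-modelling shape: build
a model object from data, call ``fit()``, receive a results object carrying
the estimates, diagnostics and a ``summary()`` table. The functional
building blocks (``register_rigid``, ``run_pair`` ...) remain available in
their own modules; these classes orchestrate them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport
from .image import ImageVolume, RoiBox
from .metrics import SamplingDomain, build_joint_histogram, metric_mi, metric_ncc, metric_nmi
from .phantom import PhantomSpec, generate_pair
from .pipeline import ALGORITHMS, PipelineConfig, run_pair
from .preprocess import BodyMask
from .registration import RegistrationConfig, register_bspline, register_rigid
from .transforms import CompositeTransform, RigidTransform, SpatialTransform

__all__ = [
    "RegistrationModel",
    "RegistrationResults",
    "CbctCorrectionModel",
    "CbctCorrectionResults",
]


@dataclasses.dataclass
class RegistrationResults:
    """Fitted spatial transform plus goodness-of-fit diagnostics."""

    transform: SpatialTransform
    model: "RegistrationModel"
    metric_name: str
    metric_initial: float
    metric_final: float

    def summary(self) -> str:
        lines = [
            "Registration Results",
            "=" * 44,
            f"mode:            {self.model.mode}",
            f"metric:          {self.metric_name}",
            f"metric initial:  {self.metric_initial: .6f}",
            f"metric final:    {self.metric_final: .6f}",
        ]
        t = self.transform
        if isinstance(t, CompositeTransform):
            lines.append(f"deformation grid: {t.deform.coefficients.shape[1:]}")
            lines.append(f"max |control displacement|: {t.deform.max_coefficient():.2f} mm")
            t = t.base
        if isinstance(t, RigidTransform):
            ax = np.degrees(t.angles)
            lines.append(f"rotation (deg, z/y/x):    {ax[0]: .3f} {ax[1]: .3f} {ax[2]: .3f}")
            tr = t.translation
            lines.append(f"translation (mm, z/y/x):  {tr[0]: .2f} {tr[1]: .2f} {tr[2]: .2f}")
        return "\n".join(lines)


class RegistrationModel:
    """Estimate the spatial transform aligning a moving volume to a fixed one.

    Parameters
    ----------
    fixed, moving : ImageVolume
        Preprocessed volumes; the transform maps fixed-image points into the
        moving image (so the moving image can be resampled onto the fixed
        grid).
    mode : {"rigid", "deformable"}
        Rigid 6-DOF (always MI-driven) or rigid + B-spline free-form.
    config : RegistrationConfig, optional
        Metric, pyramid, grid and optimizer settings.
    fixed_mask : ndarray of bool, optional
        Restrict metric sampling to the fixed-image body.
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        mode: str = "deformable",
        config: RegistrationConfig | None = None,
        fixed_mask: np.ndarray | None = None,
    ):
        if mode not in ("rigid", "deformable"):
            raise ValueError("mode must be 'rigid' or 'deformable'")
        self.fixed = fixed
        self.moving = moving
        self.mode = mode
        self.config = config if config is not None else RegistrationConfig()
        self.fixed_mask = fixed_mask

    def _metric_value(self, transform: SpatialTransform) -> float:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 999]))
        dom = SamplingDomain.random(
            self.fixed, min(20000, int(np.prod(self.fixed.shape))), rng, mask=self.fixed_mask
        )
        if cfg.metric == "ncc":
            return metric_ncc(self.fixed, self.moving, transform, dom)
        h = build_joint_histogram(self.fixed, self.moving, transform, dom, bins=cfg.bins)
        return metric_mi(h) if cfg.metric == "mi" else metric_nmi(h)

    def fit(self, init: SpatialTransform | None = None) -> RegistrationResults:
        from .transforms import IdentityTransform

        initial = self._metric_value(init if init is not None else IdentityTransform())
        if self.mode == "rigid":
            transform: SpatialTransform = register_rigid(
                self.fixed, self.moving, self.config, fixed_mask=self.fixed_mask
            )
        else:
            rigid = init
            if rigid is None:
                rigid_cfg = dataclasses.replace(self.config, metric="mi")
                rigid = register_rigid(self.fixed, self.moving, rigid_cfg, fixed_mask=self.fixed_mask)
            transform = register_bspline(
                self.fixed, self.moving, rigid, self.config, fixed_mask=self.fixed_mask
            )
        final = self._metric_value(transform)
        return RegistrationResults(
            transform=transform,
            model=self,
            metric_name="mi" if self.mode == "rigid" else self.config.metric,
            metric_initial=initial,
            metric_final=final,
        )


@dataclasses.dataclass
class CbctCorrectionResults:
    """Corrected CBCT volume(s) and their evaluation reports, per arm."""

    corrected: dict  # algorithm -> ImageVolume
    reports: dict  # algorithm -> EvaluationReport

    def summary(self) -> str:
        rows = []
        for algo, rep in self.reports.items():
            rows.append(
                {
                    "algorithm": algo,
                    "V_err before HM [HU]": round(rep.v_err_before, 2),
                    "V_err after HM [HU]": round(rep.v_err_after, 2),
                }
            )
        table = pd.DataFrame(rows).to_string(index=False)
        return "CBCT Correction Results\n" + "=" * 46 + "\n" + table

    def report(self, algo: str) -> EvaluationReport:
        return self.reports[algo]


class CbctCorrectionModel:
    """Full correction workflow for one pCT/CBCT pair as a fittable model.

    Construct from volumes (``CbctCorrectionModel(pct, cbct)``) or from a
    phantom specification (:meth:`from_phantom`), then ``fit()`` one or more
    algorithm arms.
    """

    def __init__(
        self,
        pct: ImageVolume,
        cbct: ImageVolume,
        config: PipelineConfig | None = None,
        rois: list[RoiBox] | None = None,
    ):
        self.pct = pct
        self.cbct = cbct
        self.config = config if config is not None else PipelineConfig()
        self.rois = rois

    @classmethod
    def from_phantom(
        cls, spec: PhantomSpec | None = None, config: PipelineConfig | None = None
    ) -> "CbctCorrectionModel":
        spec = spec if spec is not None else (config.phantom if config else PhantomSpec())
        pair = generate_pair(spec)
        model = cls(pair["pct"], pair["cbct"], config=config, rois=pair["rois_cbct"])
        model.phantom_pair = pair
        return model

    def fit(self, algorithms: tuple[str, ...] | None = None) -> CbctCorrectionResults:
        algos = algorithms if algorithms is not None else self.config.algorithms
        corrected: dict = {}
        reports: dict = {}
        for algo in algos:
            vol, rep = run_pair(self.config, self.pct, self.cbct, algo, rois=self.rois)
            corrected[algo] = vol
            reports[algo] = rep
        return CbctCorrectionResults(corrected=corrected, reports=reports)
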
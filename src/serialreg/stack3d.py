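"""Sequential bidirectional 3D registration with deformation validation.

Every non-reference section is registered to its already-registered
neighbor, outward from the reference layer in both directions.  Each pair's
total deformation field is validated against the mean-deformation bound
alpha: rejected pairs pass the original section through unchanged, which
stops over-deformation from accumulating along the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from .bspline import BSplineField, warp_image
from .coarse_registration import (
    GlobalTransform2D,
    detect_keypoints,
    identity_transform,
    match_descriptors,
    ransac_transform,
)
from .elastic_registration import (
    ElasticParams,
    EnergyWeights,
    PairElasticResult,
    register_elastic,
)
from .errors import DomainError, SerialRegError
from .imaging_io import SectionStack
from .preprocess import (
    StainMatrix,
    build_stain_matrix,
    extract_feature_image,
    normalize_image,
)

__all__ = [
    "ValidationVerdict",
    "PairRegistration",
    "StackRegistrationReport",
    "mean_deformation",
    "validate",
    "register_pair",
    "register_stack",
    "choose_reference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationVerdict:
    mean_deformation: float
    alpha: float
    accepted: bool


@dataclass
class PairRegistration:
    source_index: int
    target_index: int
    coarse: GlobalTransform2D
    elastic: PairElasticResult | None
    total_field: BSplineField | None
    verdict: ValidationVerdict
    output: np.ndarray


@dataclass
class StackRegistrationReport:
    reference_index: int
    pairs: list[dict] = dc_field(default_factory=list)
    parameters: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "pairs": self.pairs,
            "parameters": self.parameters,
        }


def mean_deformation(f: BSplineField) -> float:
    """Mean Euclidean distance ||g(x, y) - (x, y)|| over all domain pixels."""
    return f.mean_displacement()


def validate(f: BSplineField, alpha: float) -> ValidationVerdict:
    """Accept iff the mean geometric deformation does not exceed alpha."""
    md = mean_deformation(f)
    return ValidationVerdict(md, float(alpha), md <= alpha)


def _pair_config(cfg: Any) -> dict:
    """Normalize a config object / mapping into the knobs used per pair."""
    if cfg is not None and hasattr(cfg, "as_dict"):
        cfg = cfg.as_dict()
    elif cfg is not None and hasattr(cfg, "model_dump"):
        cfg = cfg.model_dump(by_alias=True)

    def get(path, default):
        obj = cfg
        for part in path.split("."):
            if obj is None:
                return default
            if isinstance(obj, dict):
                obj = obj.get(part)
            else:
                obj = getattr(obj, part, None)
        return default if obj is None else obj

    return {
        "p_low": get("normalize.p_low", 0.01),
        "p_high": get("normalize.p_high", 0.01),
        "feature_channel": get("feature.channel", "eosin"),
        "hematoxylin": tuple(get("stains.hematoxylin", (0.650, 0.704, 0.286))),
        "eosin": tuple(get("stains.eosin", (0.072, 0.990, 0.105))),
        "model_class": get("coarse.model_class", "similarity"),
        "ratio": get("coarse.ratio", 0.8),
        "inlier_tol": get("coarse.inlier_tol", 3.0),
        "coarse_max_iters": get("coarse.max_iters", 2000),
        "coarse_seed": get("coarse.seed", 0),
        "weights": EnergyWeights(
            get("elastic.w_img", 1.0),
            get("elastic.w_div", 0.1),
            get("elastic.w_rot", 0.1),
            get("elastic.w_cons", 1.0),
        ),
        "elastic": ElasticParams(
            spacing_px=get("elastic.spacing_px", 16.0),
            pyramid_levels=get("elastic.pyramid_levels", 3),
            max_iters=get("elastic.max_iters", 200),
            tol=get("elastic.tol", 1e-5),
            cons_stride=get("elastic.cons_stride", 4),
            img_stride=get("elastic.img_stride", 2),
        ),
        "alpha": get("stack.alpha", 50.0),
        "scope": get("validate.scope", "total"),
        "reference": get("stack.reference", "middle"),
    }


def _feature(img: np.ndarray, knobs: dict):
    norm = normalize_image(img, knobs["p_low"], knobs["p_high"])
    matrix: StainMatrix | None = None
    if norm.ndim == 3 and knobs["feature_channel"] in ("eosin", "hematoxylin"):
        matrix = build_stain_matrix(knobs["hematoxylin"], knobs["eosin"])
    return extract_feature_image(norm, matrix, knobs["feature_channel"])


def _elastic_only_deformation(coarse: GlobalTransform2D, f_st: BSplineField) -> float:
    """Mean deformation of the elastic increment relative to the coarse fit."""
    h, w = f_st.shape
    gx, gy = f_st.grid()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    back = coarse.apply(pts)  # undo the coarse component: T(f_st(x)) ~ x
    ys, xs = np.mgrid[0:h, 0:w]
    dx = back[:, 0] - xs.ravel()
    dy = back[:, 1] - ys.ravel()
    return float(np.mean(np.hypot(dx, dy)))


def register_pair(
    src: np.ndarray,
    tgt: np.ndarray,
    cfg: Any = None,
    source_index: int = 0,
    target_index: int = 1,
) -> PairRegistration:
    """Full pairwise registration: preprocess, coarse, elastic, validate.

    On acceptance the output is the original (full-color) source warped by
    the total field; on rejection it is the original source unchanged.
    Coarse failure downgrades to an identity initialization; elastic
    divergence forces a rejected verdict.
    """
    knobs = _pair_config(cfg)
    if src.shape[:2] != tgt.shape[:2]:
        raise DomainError(
            f"sections must be conformed to a common shape: {src.shape} vs {tgt.shape}"
        )
    f_src = _feature(src, knobs)
    f_tgt = _feature(tgt, knobs)

    coarse = identity_transform(knobs["model_class"])
    try:
        kp_s = detect_keypoints(f_src)
        kp_t = detect_keypoints(f_tgt)
        matches = match_descriptors(kp_s, kp_t, knobs["ratio"])
        coarse = ransac_transform(
            matches,
            knobs["model_class"],
            knobs["inlier_tol"],
            knobs["coarse_max_iters"],
            knobs["coarse_seed"],
        )
    except SerialRegError as exc:
        log.warning(
            "pair %d->%d: coarse registration failed (%s); using identity",
            source_index,
            target_index,
            exc,
        )

    try:
        elastic = register_elastic(
            f_src, f_tgt, coarse, knobs["weights"], knobs["elastic"]
        )
    except SerialRegError as exc:
        log.warning(
            "pair %d->%d: elastic stage diverged (%s); rejecting", source_index,
            target_index, exc,
        )
        verdict = ValidationVerdict(float("inf"), knobs["alpha"], False)
        return PairRegistration(
            source_index, target_index, coarse, None, None, verdict, src.copy()
        )

    total = elastic.field_fwd  # initialized from coarse, so already total
    if knobs["scope"] == "elastic_only":
        md = _elastic_only_deformation(coarse, total)
        verdict = ValidationVerdict(md, float(knobs["alpha"]), md <= knobs["alpha"])
    else:
        verdict = validate(total, knobs["alpha"])
    output = warp_image(src, total) if verdict.accepted else src.copy()
    return PairRegistration(
        source_index, target_index, coarse, elastic, total, verdict, output
    )


def choose_reference(stack: SectionStack, mode: str = "middle") -> int:
    """Reference-layer index: 'middle' (floor(N/2)), 'first', or 'index:k'."""
    n = len(stack)
    if mode == "middle":
        return n // 2
    if mode == "first":
        return 0
    if mode.startswith("index:"):
        k = int(mode.split(":", 1)[1])
        if not 0 <= k < n:
            raise DomainError(f"index error: reference {k} outside [0, {n})")
        return k
    raise ValueError(f"unknown reference mode {mode!r}")


def register_stack(
    stack: SectionStack, cfg: Any = None
) -> tuple[SectionStack, StackRegistrationReport]:
    """Register a stack outward from the reference layer, both directions.

    Each pair's target is the already-registered neighbor, so accepted
    transforms propagate and rejected ones insert the original section.
    Per-pair failures are contained; they never abort the stack.
    """
    if len(stack) < 2:
        raise DomainError("no sections: a stack needs at least 2 sections to register")
    knobs = _pair_config(cfg)
    r = choose_reference(stack, str(knobs["reference"]))
    n = len(stack)
    out: list[np.ndarray | None] = [None] * n
    out[r] = stack[r].copy()
    report = StackRegistrationReport(reference_index=r, parameters=dict(knobs_repr(knobs)))
    order = [(i, i - 1) for i in range(r + 1, n)] + [
        (i, i + 1) for i in range(r - 1, -1, -1)
    ]
    for src_i, tgt_i in order:
        pair = register_pair(stack[src_i], out[tgt_i], cfg, src_i, tgt_i)
        out[src_i] = pair.output
        report.pairs.append(
            {
                "source_index": src_i,
                "target_index": tgt_i,
                "mean_deformation": pair.verdict.mean_deformation,
                "alpha": pair.verdict.alpha,
                "accepted": pair.verdict.accepted,
                "coarse_residual": pair.coarse.mean_residual,
                "coarse_inliers": pair.coarse.n_inliers,
                "final_energy": pair.elastic.final_energy if pair.elastic else None,
            }
        )
        log.info(
            "pair %d->%d: coarse residual %.3f px, mean deformation %.3f px, %s",
            src_i,
            tgt_i,
            pair.coarse.mean_residual,
            pair.verdict.mean_deformation,
            "accepted" if pair.verdict.accepted else "rejected",
        )
    return SectionStack(out, list(stack.labels)), report


def knobs_repr(knobs: dict) -> dict:
    """JSON-serializable snapshot of the effective per-pair parameters."""
    snap = {}
    for k, v in knobs.items():
        if isinstance(v, (EnergyWeights, ElasticParams)):
            snap[k] = vars(v) if not hasattr(v, "__dataclass_fields__") else {
                f: getattr(v, f) for f in v.__dataclass_fields__
            }
        else:
            snap[k] = v
    return snap
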
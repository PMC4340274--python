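"""Plot-level kinetic analyses: saturation curves, double-reciprocal
transforms, ping-pong vs sequential line-family classification, and Hill
fits of GSH saturation data.

The double-reciprocal (Lineweaver-Burk) reading of the Grx system is the
diagnostic at the heart of the package: plotting 1/rate against 1/[PSSG]
at several GSH levels yields parallel lines when deglutathionylation is
irreversible (apparent ping-pong mechanism) but converging lines when the
step is reversible (apparent sequential mechanism).  The classifier makes
that by-eye call quantitative: lines are "parallel" when the maximum
pairwise relative slope spread is under 5%, "converging" when the spread
exceeds that and the slopes are strictly monotone in GSH.

Hill fits are done on untransformed rates (no Hill linearisation) by
Levenberg-Marquardt least squares; reciprocal-line fits use plain
unweighted OLS, matching the classical reading of such plots (a weighted
variant is available but not the default).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
import statsmodels.api as sm

from .model_core import ModelSpec
from .simulate import steady_state_flux

__all__ = [
    "AssayDataset",
    "ReciprocalPoints",
    "Line",
    "LineFamily",
    "HillFit",
    "InsufficientDataError",
    "saturation_curve",
    "to_reciprocal",
    "fit_line",
    "classify_line_family",
    "fit_hill",
    "quadratic_term",
    "read_assay_csv",
    "write_assay_csv",
]

PARALLEL_SLOPE_SPREAD = 0.05  # relative spread below which lines count as parallel


class InsufficientDataError(ValueError):
    """Fewer usable points than an analysis requires."""


@dataclass
class AssayDataset:
    """Initial-rate dataset: one varied concentration axis vs steady rate.

    ``points`` are (x in uM, rate in uM/s, optional sd in uM/s) tuples;
    replicate measurements repeat the same x.  ``fixed`` records the
    clamped background concentrations, ``meta`` free-text provenance.
    """

    points: list[tuple]  # (x, rate) or (x, rate, sd)
    varied_species: str
    fixed: dict[str, float] = field(default_factory=dict)
    meta: str = ""

    def __post_init__(self) -> None:
        cleaned = []
        for p in self.points:
            x, rate = float(p[0]), float(p[1])
            sd = float(p[2]) if len(p) > 2 and p[2] is not None else None
            if x < 0:
                raise ValueError(f"negative concentration {x}")
            if rate < 0:
                raise ValueError(f"negative rate {rate}")
            cleaned.append((x, rate, sd) if sd is not None else (x, rate))
        self.points = cleaned

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def sds(self) -> np.ndarray | None:
        sds = [p[2] if len(p) > 2 else None for p in self.points]
        if any(s is None for s in sds):
            return None
        return np.array(sds)


@dataclass(frozen=True)
class ReciprocalPoints:
    """Double-reciprocal transform (1/x, 1/rate) of an assay dataset."""

    inv_x: np.ndarray
    inv_rate: np.ndarray
    n_excluded: int  # points dropped for zero/near-zero x or rate


@dataclass(frozen=True)
class Line:
    gsh: float
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class LineFamily:
    lines: tuple[Line, ...]
    classification: str  # "parallel" | "converging" | "neither"
    slope_spread: float  # max pairwise relative slope difference


@dataclass(frozen=True)
class HillFit:
    V: float
    K_half: float
    n: float
    r2: float
    converged: bool
    meta: str = ""


# ---------------------------------------------------------------------------
# curve generation and transforms
# ---------------------------------------------------------------------------


def saturation_curve(
    model: ModelSpec,
    varied_species: str,
    values: Sequence[float],
) -> AssayDataset:
    """Steady-state rate of the model's measured reaction at each value of
    one clamped species."""
    points = []
    for value in values:
        if value < 0:
            raise ValueError(f"concentration grid value {value} is negative")
        variant = model.with_clamped(varied_species, float(value))
        try:
            rate = steady_state_flux(variant)
        except Exception as exc:
            raise RuntimeError(
                f"steady-state solve failed at {varied_species} = {value} uM"
            ) from exc
        points.append((float(value), rate))
    fixed = {k: v for k, v in model.clamped.items() if k != varied_species}
    return AssayDataset(
        points=points,
        varied_species=varied_species,
        fixed=fixed,
        meta=f"saturation curve of model {model.name}",
    )


def to_reciprocal(dataset: AssayDataset, eps: float = 1e-300) -> ReciprocalPoints:
    """Transform to (1/x, 1/rate), dropping zero/near-zero points."""
    usable = [(x, r) for x, r, *_ in [tuple(p) for p in dataset.points] if x > eps and r > eps]
    n_excluded = len(dataset.points) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable points after excluding "
            f"{n_excluded} zero/near-zero points; need at least 3"
        )
    xs = np.array([1.0 / x for x, _ in usable])
    ys = np.array([1.0 / r for _, r in usable])
    return ReciprocalPoints(inv_x=xs, inv_rate=ys, n_excluded=n_excluded)


def fit_line(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float, float]:
    """OLS (optionally weighted) line fit; returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 points for a line fit")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    W = np.diag(w)
    A = np.column_stack([x, np.ones_like(x)])
    coeffs, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(w) * y, rcond=None)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    predicted = slope * x + intercept
    ss_res = float(np.sum(w * (y - predicted) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def quadratic_term(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS quadratic fit y ~ 1 + x + x^2; returns (coefficient, p-value).

    Used to test whether a reciprocal plot is genuinely curved (the
    1/GSH^2 term of the wild-type law) rather than linear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 points for a quadratic test")
    design = sm.add_constant(np.column_stack([x, x ** 2]))
    fit = sm.OLS(y, design).fit()
    return float(fit.params[2]), float(fit.pvalues[2])


# ---------------------------------------------------------------------------
# line-family classification (ping-pong vs sequential)
# ---------------------------------------------------------------------------


def classify_line_family(
    datasets: Iterable[AssayDataset],
    weighted: bool = False,
) -> LineFamily:
    """Classify reciprocal lines at several GSH levels as parallel,
    converging, or neither.

    Each dataset must carry its GSH level in ``fixed['GSH']``.  The
    classification is invariant to dataset order and to uniform rescaling
    of the rate unit (slopes scale together, leaving the relative spread
    unchanged).
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise InsufficientDataError("need at least 2 datasets to classify")
    lines = []
    for ds in datasets:
        if "GSH" not in ds.fixed:
            raise ValueError(
                "each dataset must record its GSH level in fixed['GSH']"
            )
        rec = to_reciprocal(ds)
        weights = None
        if weighted and ds.sds is not None:
            # delta-method weights for 1/rate when sds accompany the rates
            usable = [p for p in ds.points if p[0] > 0 and p[1] > 0]
            weights = np.array([(p[1] ** 2 / p[2]) ** 2 for p in usable])
        slope, intercept, r2 = fit_line(rec.inv_x, rec.inv_rate, weights)
        lines.append(Line(gsh=ds.fixed["GSH"], slope=slope, intercept=intercept, r2=r2))
    lines.sort(key=lambda ln: ln.gsh)
    slopes = np.array([ln.slope for ln in lines])
    mean_abs = float(np.mean(np.abs(slopes)))
    spread = float((slopes.max() - slopes.min()) / mean_abs) if mean_abs > 0 else 0.0
    if spread < PARALLEL_SLOPE_SPREAD:
        classification = "parallel"
    else:
        diffs = np.diff(slopes)
        monotone = bool(np.all(diffs > 0) or np.all(diffs < 0))
        classification = "converging" if monotone else "neither"
    return LineFamily(
        lines=tuple(lines), classification=classification, slope_spread=spread
    )


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------


def _hill(x: np.ndarray, V: float, K_half: float, n: float) -> np.ndarray:
    sigma_n = (x / K_half) ** n
    return V * sigma_n / (1.0 + sigma_n)


def fit_hill(dataset: AssayDataset, fix_n: float | None = None) -> HillFit:
    """Levenberg-Marquardt fit of V*sigma^n/(1+sigma^n) to a saturation curve.

    Initialised at V = max rate, K_half = interpolated x at half-maximal
    rate, n = 1.  Non-convergence is flagged on the result, not raised;
    a half-saturation estimate outside the x-range is noted in ``meta``.
    """
    x = dataset.x
    y = dataset.rates
    mask = x > 0
    x, y = x[mask], y[mask]
    if x.size < 5:
        raise InsufficientDataError(
            f"need at least 5 positive-concentration points, got {x.size}"
        )
    order = np.argsort(x)
    x, y = x[order], y[order]
    v_init = float(y.max())
    half = v_init / 2.0
    k_init = float(np.interp(half, y, x)) if y.max() > y.min() else float(np.median(x))
    k_init = max(k_init, x.min() * 1e-3)
    meta = ""
    if not (x.min() <= k_init <= x.max()):
        meta = "warning: half-saturation estimate outside the sampled x-range"

    model = lmfit.Model(_hill)
    params = model.make_params(
        V=dict(value=v_init, min=0.0),
        K_half=dict(value=k_init, min=0.0),
        n=dict(value=1.0 if fix_n is None else fix_n, min=0.05, max=10.0),
    )
    if fix_n is not None:
        params["n"].set(vary=False)
    try:
        result = model.fit(y, params, x=x, method="leastsq")
        converged = bool(result.success)
    except Exception:
        return HillFit(
            V=v_init, K_half=k_init, n=float(fix_n or 1.0),
            r2=0.0, converged=False, meta=meta + " fit raised",
        )
    predicted = result.best_fit
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HillFit(
        V=float(result.params["V"].value),
        K_half=float(result.params["K_half"].value),
        n=float(result.params["n"].value),
        r2=r2,
        converged=converged,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# header `x_uM,rate_uM_per_s[,sd]`, preceded by `# key: value` comment
# lines carrying varied_species, fixed concentrations and meta; the
# reader and writer round-trip exactly (x bit-exact via repr).


def write_assay_csv(dataset: AssayDataset, path_or_buffer) -> None:
    buf = io.StringIO()
    buf.write(f"# varied_species: {dataset.varied_species}\n")
    for name in sorted(dataset.fixed):
        buf.write(f"# fixed.{name}: {dataset.fixed[name]!r}\n")
    if dataset.meta:
        for line in dataset.meta.splitlines():
            buf.write(f"# meta: {line}\n")
    has_sd = any(len(p) > 2 for p in dataset.points)
    buf.write("x_uM,rate_uM_per_s,sd\n" if has_sd else "x_uM,rate_uM_per_s\n")
    for p in dataset.points:
        row = ",".join(repr(float(v)) for v in p)
        buf.write(row + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "w") as fh:
            fh.write(text)


def read_assay_csv(path_or_buffer) -> AssayDataset:
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    varied = ""
    fixed: dict[str, float] = {}
    meta_lines: list[str] = []
    points: list[tuple] = []
    header_seen = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, value = body.split(":", 1)
            key, value = key.strip(), value.strip()
            if key == "varied_species":
                varied = value
            elif key.startswith("fixed."):
                fixed[key[len("fixed."):]] = float(value)
            elif key == "meta":
                meta_lines.append(value)
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        fields = line.split(",")
        points.append(tuple(float(f) for f in fields if f != ""))
    if not varied:
        raise ValueError("assay CSV lacks a '# varied_species:' header line")
    return AssayDataset(
        points=points, varied_species=varied, fixed=fixed, meta="\n".join(meta_lines)
    )
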
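"""Three-axis nomogram linking prior probability, P value and minimum posterior.

The chart is a Fagan-style alignment diagram.  Three parallel vertical
axes sit at normalized abscissas 0, 1/2 and 1.  Ordinates are

    left   axis:  y = -logit(q)        (prior probability of H0)
    middle axis:  y = ln(BF_min(p))/2  (P value, through its minimum Bayes factor)
    right  axis:  y =  logit(pi)       (minimum posterior probability of H0)

With these transforms the straight-edge property is exact: the three
points are collinear precisely when logit(pi) = logit(q) + ln BF_min(p),
which is Bayes' theorem on the log-odds scale.  The factor 1/2 on the
middle axis is what places it midway between the outer axes: the midpoint
ordinate of the chord from (0, -logit q) to (1, logit pi) equals
[logit(pi) - logit(q)]/2 = ln(BF)/2.

Only P values below 1/e appear on the middle axis: above that cutoff the
minimum Bayes factor is 1 and the nomogram has nothing to move.  All
middle-axis ordinates are therefore <= 0 — the chart only ever moves the
posterior below the prior, which is why the left and right probability
scales are deliberately *not* identical (P values measure evidence
against, never for, the null hypothesis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .calibration import CalibrationMethod, Method, PValue, min_bf
from .conversion import solve

__all__ = [
    "DEFAULT_PROB_TICKS",
    "DEFAULT_P_TICKS",
    "NomogramGeometry",
    "NomogramLine",
    "build_geometry",
    "read_off",
    "render",
]

_P_CUTOFF = 1.0 / math.e

DEFAULT_PROB_TICKS: tuple[float, ...] = (
    0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
    0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 0.995, 0.999,
)
DEFAULT_P_TICKS: tuple[float, ...] = (
    0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 1e-4, 1e-5, 1e-6,
)

# Figure-style default palette for successive lines: green, red, blue.
_LINE_COLORS = ("#2ca02c", "#d62728", "#1f77b4")


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


@dataclass(frozen=True)
class NomogramGeometry:
    """Axis transforms, tick sets and clip range of the three-axis chart.

    Abscissas are fixed at 0 (prior), 1/2 (P value) and 1 (posterior) in
    normalized chart coordinates; `clip` bounds the ordinate on every axis.
    """

    method: CalibrationMethod
    prior_range: tuple[float, float]
    p_range: tuple[float, float]
    posterior_range: tuple[float, float]
    prior_ticks: tuple[float, ...]
    p_ticks: tuple[float, ...]
    posterior_ticks: tuple[float, ...]
    clip: float

    x_left: float = 0.0
    x_mid: float = 0.5
    x_right: float = 1.0

    def y_left(self, q: float) -> float:
        """Ordinate of a prior probability; increases as q decreases."""
        return -_logit(q)

    def y_mid(self, p: float) -> float:
        """Ordinate of a P value: half the log minimum Bayes factor (always <= 0)."""
        return 0.5 * math.log(min_bf(self.method, PValue(p)).bf)

    def y_right(self, pi: float) -> float:
        """Ordinate of a posterior probability; mirror image of the left transform."""
        return _logit(pi)


@dataclass(frozen=True)
class NomogramLine:
    """A straight-edge line: three values satisfying Bayes' theorem."""

    prior: float
    p: float
    posterior: float
    color: str = "#d62728"
    label: str | None = None


def build_geometry(
    method: CalibrationMethod | Method = Method.SBB,
    prior_range: tuple[float, float] = (0.001, 0.999),
    p_range: tuple[float, float] = (1e-6, 0.3),
    posterior_range: tuple[float, float] = (0.001, 0.999),
    prior_ticks: tuple[float, ...] = DEFAULT_PROB_TICKS,
    p_ticks: tuple[float, ...] = DEFAULT_P_TICKS,
    posterior_ticks: tuple[float, ...] = DEFAULT_PROB_TICKS,
    clip: float = 7.0,
) -> NomogramGeometry:
    """Construct the chart geometry, by default on the SBB calibration.

    The SBB bound is the default because it is not tied to a specific test
    statistic; any other calibration can be substituted.  The P-value axis
    must lie strictly inside (0, 1/e).
    """
    if isinstance(method, Method):
        method = CalibrationMethod(method)
    for name, (lo, hi) in (("prior", prior_range), ("posterior", posterior_range)):
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"{name} axis range must satisfy 0 < lo < hi < 1, got ({lo}, {hi})")
    lo, hi = p_range
    if not (0.0 < lo < hi < _P_CUTOFF):
        raise ValueError(
            f"P-value axis range must lie inside (0, 1/e ~ {_P_CUTOFF:.4f}); got ({lo}, {hi})"
        )
    return NomogramGeometry(
        method=method,
        prior_range=prior_range,
        p_range=p_range,
        posterior_range=posterior_range,
        prior_ticks=tuple(t for t in prior_ticks if prior_range[0] <= t <= prior_range[1]),
        p_ticks=tuple(t for t in p_ticks if p_range[0] <= t <= p_range[1]),
        posterior_ticks=tuple(t for t in posterior_ticks if posterior_range[0] <= t <= posterior_range[1]),
        clip=clip,
    )


def read_off(
    geometry: NomogramGeometry,
    prior: float | None = None,
    p: float | None = None,
    posterior: float | None = None,
    color: str | None = None,
    label: str | None = None,
) -> NomogramLine:
    """Solve the straight-edge problem: fix two quantities, read off the third.

    The solved value makes the three plotted points exactly collinear in
    chart coordinates; a posterior target at or above the prior raises
    `NoSolutionError` (the line would need an off-scale P value).
    """
    fixed = {"prior": prior, "p": p, "posterior": posterior}
    given = {k: v for k, v in fixed.items() if v is not None}
    if len(given) != 2:
        raise ValueError(f"exactly two of prior/p/posterior must be fixed, got {sorted(given)}")
    ranges = {"prior": geometry.prior_range, "p": geometry.p_range, "posterior": geometry.posterior_range}
    for k, v in given.items():
        lo, hi = ranges[k]
        if not lo <= v <= hi:
            raise ValueError(f"{k}={v} lies outside the {k} axis range ({lo}, {hi})")
    result = solve(prior=prior, p=p, posterior=posterior, method=geometry.method)
    fixed[{"posterior": "posterior", "prior": "prior", "p_value": "p"}[result.solved_quantity]] = result.value
    return NomogramLine(
        prior=fixed["prior"],
        p=fixed["p"],
        posterior=fixed["posterior"],
        color=color or "#d62728",
        label=label,
    )


def assign_default_colors(lines: list[NomogramLine]) -> list[NomogramLine]:
    """Cycle the green/red/blue palette over lines that kept the default color."""
    out = []
    for i, ln in enumerate(lines):
        if ln.color == "#d62728":
            ln = replace(ln, color=_LINE_COLORS[i % len(_LINE_COLORS)])
        out.append(ln)
    return out


# ---------------------------------------------------------------------------
# Rendering


@dataclass(frozen=True)
class _Layout:
    width: int = 720
    height: int = 560
    margin_left: int = 120
    margin_right: int = 140
    margin_top: int = 70
    margin_bottom: int = 30

    def px(self, x: float) -> float:
        return self.margin_left + x * (self.width - self.margin_left - self.margin_right)

    def py(self, u: float, clip: float) -> float:
        frac = (clip - u) / (2.0 * clip)
        return self.margin_top + frac * (self.height - self.margin_top - self.margin_bottom)


def _fmt_tick(v: float) -> str:
    return f"{v:g}"


def _svg_text(x: float, y: float, s: str, anchor: str = "middle", size: int = 11, bold: bool = False) -> str:
    weight = ' font-weight="bold"' if bold else ""
    return (
        f'<text x="{x:.2f}" y="{y:.2f}" text-anchor="{anchor}" '
        f'font-family="Helvetica, Arial, sans-serif" font-size="{size}"{weight}>{s}</text>'
    )


def _render_svg(geometry: NomogramGeometry, lines: list[NomogramLine], layout: _Layout) -> str:
    g, L = geometry, layout
    clip = g.clip
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="{L.width}" height="{L.height}" '
        f'viewBox="0 0 {L.width} {L.height}">',
        f'<rect width="{L.width}" height="{L.height}" fill="white"/>',
        "<defs><clipPath id=\"plot\">"
        f'<rect x="{L.margin_left}" y="{L.margin_top}" '
        f'width="{L.width - L.margin_left - L.margin_right}" '
        f'height="{L.height - L.margin_top - L.margin_bottom}"/>'
        "</clipPath></defs>",
    ]

    # straight-edge lines first so axes sit on top
    parts.append('<g clip-path="url(#plot)">')
    for ln in lines:
        x1, y1 = L.px(g.x_left), L.py(g.y_left(ln.prior), clip)
        x2, y2 = L.px(g.x_right), L.py(g.y_right(ln.posterior), clip)
        parts.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{ln.color}" stroke-width="1.8"/>'
        )
    parts.append("</g>")

    axes = [
        (g.x_left, "Prior probability", [(t, g.y_left(t)) for t in g.prior_ticks], "end", -8),
        (g.x_mid, "P value", [(t, g.y_mid(t)) for t in g.p_ticks], "end", -8),
        (g.x_right, "Min. posterior probability", [(t, g.y_right(t)) for t in g.posterior_ticks], "start", 8),
    ]
    for x, title, ticks, anchor, dx in axes:
        xp = L.px(x)
        parts.append(
            f'<line x1="{xp:.2f}" y1="{L.py(clip, clip):.2f}" x2="{xp:.2f}" '
            f'y2="{L.py(-clip, clip):.2f}" stroke="black" stroke-width="1.2"/>'
        )
        parts.append(_svg_text(xp, L.margin_top - 28, title, size=12, bold=True))
        for value, u in ticks:
            if abs(u) > clip:
                continue
            yp = L.py(u, clip)
            parts.append(
                f'<line x1="{xp - 4:.2f}" y1="{yp:.2f}" x2="{xp + 4:.2f}" y2="{yp:.2f}" '
                f'stroke="black" stroke-width="1"/>'
            )
            parts.append(_svg_text(xp + dx, yp + 3.5, _fmt_tick(value), anchor=anchor))

    labeled = [ln for ln in lines if ln.label]
    if labeled:
        ly = L.height - L.margin_bottom - 16 * len(labeled) - 6
        for i, ln in enumerate(labeled):
            y0 = ly + 16 * i
            parts.append(
                f'<line x1="{L.margin_left + 6}" y1="{y0:.2f}" x2="{L.margin_left + 30}" '
                f'y2="{y0:.2f}" stroke="{ln.color}" stroke-width="1.8"/>'
            )
            parts.append(_svg_text(L.margin_left + 36, y0 + 3.5, ln.label, anchor="start"))

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _render_png(geometry: NomogramGeometry, lines: list[NomogramLine], path: str, layout: _Layout) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    g = geometry
    clip = g.clip
    fig, ax = plt.subplots(figsize=(layout.width / 96, layout.height / 96), dpi=96)
    for ln in lines:
        ax.plot(
            [g.x_left, g.x_right],
            [g.y_left(ln.prior), g.y_right(ln.posterior)],
            color=ln.color,
            lw=1.8,
            label=ln.label,
        )
    specs = [
        (g.x_left, "Prior probability", [(t, g.y_left(t)) for t in g.prior_ticks], "right", -0.015),
        (g.x_mid, "P value", [(t, g.y_mid(t)) for t in g.p_ticks], "right", -0.015),
        (g.x_right, "Min. posterior probability", [(t, g.y_right(t)) for t in g.posterior_ticks], "left", 0.015),
    ]
    for x, title, ticks, ha, dx in specs:
        ax.plot([x, x], [-clip, clip], color="black", lw=1.2)
        ax.text(x, clip * 1.12, title, ha="center", fontsize=10, fontweight="bold")
        for value, u in ticks:
            if abs(u) > clip:
                continue
            ax.plot([x - 0.008, x + 0.008], [u, u], color="black", lw=1)
            ax.text(x + dx, u, _fmt_tick(value), ha=ha, va="center", fontsize=8)
    if any(ln.label for ln in lines):
        ax.legend(loc="lower left", fontsize=8, frameon=False)
    ax.set_xlim(-0.18, 1.2)
    ax.set_ylim(-clip * 1.05, clip * 1.25)
    ax.axis("off")
    fig.savefig(path, dpi=96)
    plt.close(fig)


def render(
    geometry: NomogramGeometry,
    lines: list[NomogramLine] | None = None,
    path: str = "nomogram.svg",
    format: str | None = None,
    layout: _Layout | None = None,
) -> str:
    """Write the chart to an SVG or PNG file and return the path.

    SVG output is byte-deterministic for a fixed geometry and line list
    (no timestamps or random ids); PNG is rasterized from the same
    geometry through matplotlib.
    """
    lines = assign_default_colors(list(lines or []))
    layout = layout or _Layout()
    fmt = (format or ("png" if str(path).lower().endswith(".png") else "svg")).lower()
    if fmt == "svg":
        svg = _render_svg(geometry, lines, layout)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(svg)
    elif fmt == "png":
        _render_png(geometry, lines, path, layout)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'svg' or 'png'")
    return str(path)
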
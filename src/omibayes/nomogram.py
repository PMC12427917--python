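"""Fagan nomogram construction and SVG rendering.

A Fagan nomogram is three aligned vertical scales: pre-test probability
on the left (inverted logit scale), likelihood ratio in the middle
(log10 scale at half span), post-test probability on the right (logit
scale).  A straight line from the pre-test probability through the LR
crosses the right axis at the post-test probability — the geometry *is*
the odds-scale arithmetic:

    left  y = -log10(prior odds)
    mid   y = log10(LR) / 2
    right y = +log10(posterior odds)

With the axes at abscissae 0, 1, 2, the line through the left and middle
anchors extrapolates to ``2*y_mid - y_left = log10(prior odds * LR)`` at
the right axis — exactly the posterior odds.  The half-span middle axis
is what makes the construction work; it is forced by collinearity, not a
style choice.

Rendering is plain SVG 1.1 text with no timestamps, so identical inputs
produce byte-identical documents (diffable in tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import UpdateTrace, apply_lr, odds_to_prob, prob_to_odds

__all__ = ["NomogramLayout", "layout", "render", "PROB_MIN", "PROB_MAX", "LR_MIN", "LR_MAX"]

# axis ranges: probabilities 0.1%-99.9%, LRs 0.001-1000
PROB_MIN, PROB_MAX = 0.001, 0.999
LR_MIN, LR_MAX = 0.001, 1000.0

# classical tick sets (percent / LR)
PROB_TICKS_PERCENT = (
    0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0,
    30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 85.0, 90.0, 93.0, 95.0, 97.0,
    98.0, 99.0, 99.3, 99.5, 99.7, 99.8, 99.9,
)
LR_TICKS = (
    0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5,
    1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0,
)


def left_axis_y(p: float) -> float:
    """Pre-test axis ordinate: -log10 of the prior odds (inverted logit)."""
    return -math.log10(prob_to_odds(p))


def right_axis_y(p: float) -> float:
    """Post-test axis ordinate: +log10 of the posterior odds (logit)."""
    return math.log10(prob_to_odds(p))


def mid_axis_y(lr: float) -> float:
    """LR axis ordinate: log10(LR) at half span."""
    return math.log10(lr) / 2.0


@dataclass(frozen=True)
class NomogramLayout:
    """Anchor geometry for one update drawn on a Fagan nomogram."""

    prior: float
    lr: float
    posterior: float
    left_y: float
    mid_y: float
    right_y: float
    clipped: bool = False

    def read_off(self) -> float:
        """Posterior recovered *geometrically*: extend the line through the
        left and middle anchors to the right axis and invert the scale."""
        y_right = 2.0 * self.mid_y - self.left_y
        return odds_to_prob(10.0 ** y_right)


def _clip(value: float, lo: float, hi: float, what: str) -> tuple[float, bool]:
    if value < lo or value > hi:
        warnings.warn(
            f"{what} {value} outside the nomogram range [{lo}, {hi}]; clipped",
            stacklevel=3,
        )
        return min(hi, max(lo, value)), True
    return value, False


def layout(prior: float, lr: float) -> NomogramLayout:
    """Compute the anchor triple for one (prior, LR) update.

    Out-of-range values are clipped to the axis ranges with a warning,
    never silently.  The three anchors are collinear by construction and
    the geometric read-off equals the odds-scale arithmetic to 1e-9.
    """
    prior, c1 = _clip(prior, PROB_MIN, PROB_MAX, "prior probability")
    lr, c2 = _clip(lr, LR_MIN, LR_MAX, "likelihood ratio")
    posterior = apply_lr(prior, lr)
    return NomogramLayout(
        prior=prior,
        lr=lr,
        posterior=posterior,
        left_y=left_axis_y(prior),
        mid_y=mid_axis_y(lr),
        right_y=right_axis_y(posterior),
        clipped=c1 or c2,
    )


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

# fixed default style; overridable via render() kwargs
STYLE = {
    "width": 480,
    "height": 640,
    "margin": 60,
    "axis_color": "#333333",
    "line_color": "#b22222",
    "chain_colors": ("#b22222", "#1f6fb2", "#2e8b57", "#8b6914", "#6a3db2"),
    "font": "Helvetica, Arial, sans-serif",
    "font_size": 9,
}

_Y_SPAN = 3.0  # |log10 odds| covered by the probability axes


def _fmt(x: float) -> str:
    return f"{x:.3f}".rstrip("0").rstrip(".")


class _Svg:
    def __init__(self, width: int, height: int) -> None:
        self.parts: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{width}" height="{height}" '
            f'viewBox="0 0 {width} {height}">',
        ]

    def line(self, x1, y1, x2, y2, color, width=1.0, dash=None) -> None:
        d = f' stroke-dasharray="{dash}"' if dash else ""
        self.parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{color}" stroke-width="{_fmt(width)}"{d}/>'
        )

    def circle(self, cx, cy, r, color) -> None:
        self.parts.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="{color}"/>'
        )

    def text(self, x, y, s, font, size, anchor="start", color="#333333") -> None:
        self.parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="{font}" '
            f'font-size="{size}" text-anchor="{anchor}" fill="{color}">{s}</text>'
        )

    def document(self) -> str:
        return "\n".join(self.parts + ["</svg>"]) + "\n"


def _build(layouts: Sequence[NomogramLayout], labels: Sequence[str], style: dict) -> str:
    w, h, m = style["width"], style["height"], style["margin"]
    font, fs = style["font"], style["font_size"]
    axis_x = {0: m, 1: w / 2.0, 2: w - m}

    def to_svg_y(y: float) -> float:
        # math y in [-_Y_SPAN, _Y_SPAN] maps top (+) to bottom (-)
        return m + (_Y_SPAN - y) / (2.0 * _Y_SPAN) * (h - 2.0 * m)

    svg = _Svg(w, h)
    for x in axis_x.values():
        svg.line(x, to_svg_y(_Y_SPAN), x, to_svg_y(-_Y_SPAN), style["axis_color"], 1.2)
    svg.text(axis_x[0], m - 24, "pre-test P (%)", font, fs + 1, "middle")
    svg.text(axis_x[1], m - 24, "likelihood ratio", font, fs + 1, "middle")
    svg.text(axis_x[2], m - 24, "post-test P (%)", font, fs + 1, "middle")

    for pct in PROB_TICKS_PERCENT:
        p = pct / 100.0
        yl, yr = to_svg_y(left_axis_y(p)), to_svg_y(right_axis_y(p))
        label = f"{pct:g}"
        svg.line(axis_x[0] - 4, yl, axis_x[0], yl, style["axis_color"])
        svg.text(axis_x[0] - 7, yl + fs / 3.0, label, font, fs, "end")
        svg.line(axis_x[2], yr, axis_x[2] + 4, yr, style["axis_color"])
        svg.text(axis_x[2] + 7, yr + fs / 3.0, label, font, fs, "start")
    for lr in LR_TICKS:
        ym = to_svg_y(mid_axis_y(lr))
        svg.line(axis_x[1] - 4, ym, axis_x[1] + 4, ym, style["axis_color"])
        svg.text(axis_x[1] + 7, ym + fs / 3.0, f"{lr:g}", font, fs, "start")

    colors = style["chain_colors"]
    for i, lay in enumerate(layouts):
        color = colors[i % len(colors)]
        y1, y2 = to_svg_y(lay.left_y), to_svg_y(lay.right_y)
        svg.line(axis_x[0], y1, axis_x[2], y2, color, 1.6)
        svg.circle(axis_x[0], y1, 3.0, color)
        svg.circle(axis_x[1], to_svg_y(lay.mid_y), 3.0, color)
        svg.circle(axis_x[2], y2, 3.0, color)
        if i < len(labels) and labels[i]:
            label = (
                f"{labels[i]}: {lay.prior * 100.0:.1f}% "
                f"&#215;LR {lay.lr:g} &#8594; {lay.posterior * 100.0:.1f}%"
            )
            svg.text(m, h - m + 16 + i * (fs + 3), label, font, fs, "start", color)
    return svg.document()


def render(
    layout_or_none: NomogramLayout | None,
    chain: UpdateTrace | None = None,
    path: str | Path | None = None,
    **style_overrides,
) -> str:
    """Render one update and/or a chained trace to an SVG document.

    A chained trace is drawn as a ladder on one canvas: each step's
    posterior becomes the next step's prior, with per-step labels in the
    footer.  Identical inputs produce byte-identical output (no
    timestamps, fixed float formatting).  Returns the SVG text; writes it
    to ``path`` if given (I/O failures surface with the path).
    """
    style = {**STYLE, **style_overrides}
    layouts: list[NomogramLayout] = []
    labels: list[str] = []
    if layout_or_none is not None:
        layouts.append(layout_or_none)
        labels.append("")
    if chain is not None:
        for step in chain.steps:
            layouts.append(layout(step.pre, step.lr_value))
            labels.append(step.label)
    doc = _build(layouts, labels, style)
    if path is not None:
        try:
            Path(path).write_text(doc)
        except OSError as exc:
            raise OSError(f"cannot write nomogram to {path}: {exc}") from exc
    return doc
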
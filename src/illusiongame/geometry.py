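"""Parametric illusion geometry.

Maps (illusion type, signed strength, difficulty) to a resolved drawing
plan on a normalized canvas (x, y in [-1, 1], y up) together with the
objectively correct 2AFC response.

Conventions
-----------
* ``difficulty`` is the objective difference between the two targets in
  the illusion's native unit; **larger values mean easier trials**.
* ``strength`` is signed: positive values are *incongruent* (the context
  biases perception against the correct answer), negative values are
  *congruent* (the context facilitates it), zero is a neutral context.
* Every plan can be measured back: :func:`measure_plan` recovers
  ``(difficulty, |strength|)`` from the primitives alone, which the test
  suite uses as a round-trip oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import constants as C

__all__ = [
    "Segment",
    "Circle",
    "Rect",
    "StimulusSpec",
    "GeometryPlan",
    "make_spec",
    "plan_stimulus",
    "correct_response",
    "measure_plan",
    "mirror_plan",
    "response_axis",
]


def GRAY(g: float) -> tuple:
    return (g, g, g)


BLACK = (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Segment:
    x1: float
    y1: float
    x2: float
    y2: float
    width: float = C.LINE_WIDTH
    color: tuple = BLACK
    role: str = "context"  # "target" | "context"

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    def angle_deg(self) -> float:
        """Direction angle in degrees, normalized to (-90, 90]."""
        a = math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1))
        while a <= -90.0:
            a += 180.0
        while a > 90.0:
            a -= 180.0
        return a

    def canonical(self):
        ends = sorted([(self.x1, self.y1), (self.x2, self.y2)])
        return ("segment", *ends[0], *ends[1], self.width, self.color, self.role)


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float
    color: tuple = BLACK
    fill: bool = True
    width: float = C.LINE_WIDTH  # outline stroke width when fill=False
    role: str = "context"

    def canonical(self):
        return ("circle", self.cx, self.cy, self.r, self.color, self.fill,
                self.width, self.role)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned filled rectangle; (x1, y1) lower-left, (x2, y2) upper-right."""

    x1: float
    y1: float
    x2: float
    y2: float
    color: tuple = BLACK
    role: str = "context"

    def canonical(self):
        return ("rect", self.x1, self.y1, self.x2, self.y2, self.color, self.role)


# ---------------------------------------------------------------------------
# Spec and plan
# ---------------------------------------------------------------------------
def response_axis(illusion_type: str) -> tuple:
    try:
        return C.RESPONSE_AXIS[illusion_type]
    except KeyError:
        raise ValueError(f"unknown illusion type: {illusion_type!r}") from None


@dataclass(frozen=True)
class StimulusSpec:
    illusion_type: str
    strength: float
    difficulty: float
    target_assignment: str
    is_practice: bool = False

    def __post_init__(self):
        axis = response_axis(self.illusion_type)
        if not self.difficulty > 0:
            raise ValueError("difficulty must be > 0")
        lo, hi = C.DIFFICULTY_RANGE[self.illusion_type]
        if not (lo <= self.difficulty <= hi * (1 + 1e-12)):
            raise ValueError(
                f"difficulty {self.difficulty} outside configured range "
                f"[{lo}, {hi}] for {self.illusion_type}"
            )
        if abs(self.strength) > C.STRENGTH_MAX[self.illusion_type] * (1 + 1e-12):
            raise ValueError(
                f"|strength| {abs(self.strength)} exceeds configured maximum "
                f"{C.STRENGTH_MAX[self.illusion_type]} for {self.illusion_type}"
            )
        if self.target_assignment not in axis:
            raise ValueError(
                f"target_assignment {self.target_assignment!r} not on the "
                f"response axis {axis} of {self.illusion_type}"
            )

    @property
    def congruence(self) -> str:
        if self.strength > 0:
            return "incongruent"
        if self.strength < 0:
            return "congruent"
        return "neutral"


@dataclass(frozen=True)
class GeometryPlan:
    primitives: tuple
    correct_response: str
    spec: StimulusSpec

    def targets(self) -> list:
        return [p for p in self.primitives if p.role == "target"]

    def context(self) -> list:
        return [p for p in self.primitives if p.role == "context"]

    def to_json(self) -> str:
        payload = {
            "correct_response": self.correct_response,
            "spec": asdict(self.spec),
            "primitives": [
                {"kind": type(p).__name__.lower(), **asdict(p)}
                for p in self.primitives
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "GeometryPlan":
        payload = json.loads(text)
        kinds = {"segment": Segment, "circle": Circle, "rect": Rect}
        prims = []
        for p in payload["primitives"]:
            kind = p.pop("kind")
            p["color"] = tuple(p["color"])
            prims.append(kinds[kind](**p))
        return GeometryPlan(
            primitives=tuple(prims),
            correct_response=payload["correct_response"],
            spec=StimulusSpec(**payload["spec"]),
        )


def make_spec(
    illusion_type: str,
    strength: float,
    difficulty: float,
    rng_seed: int,
    is_practice: bool = False,
) -> StimulusSpec:
    """Build a validated spec, sampling the target side from the seed."""
    axis = response_axis(illusion_type)
    rng = np.random.default_rng(rng_seed)
    target = axis[int(rng.integers(2))]
    return StimulusSpec(
        illusion_type=illusion_type,
        strength=float(strength),
        difficulty=float(difficulty),
        target_assignment=target,
        is_practice=is_practice,
    )


def correct_response(spec: StimulusSpec) -> str:
    """The objectively correct 2AFC answer: always the target's position."""
    return spec.target_assignment


# ---------------------------------------------------------------------------
# Builders. Each returns a tuple of primitives; the correct response is the
# target assignment by construction.
# ---------------------------------------------------------------------------
def _side_sign(spec: StimulusSpec) -> int:
    """+1 for right/up, -1 for left/down."""
    return 1 if spec.target_assignment in ("right", "up") else -1


def _comparison_circles(spec: StimulusSpec):
    """The two red comparison circles shared by Delboeuf and Ebbinghaus."""
    r0 = C.CIRCLE_BASE_RADIUS
    tx = _side_sign(spec)
    big = Circle(tx * C.CIRCLE_CENTERS_X, 0.0, r0 * (1 + spec.difficulty),
                 color=C.TARGET_COLOR, role="target")
    small = Circle(-tx * C.CIRCLE_CENTERS_X, 0.0, r0,
                   color=C.TARGET_COLOR, role="target")
    return big, small, r0, tx


def _build_delboeuf(spec):
    big, small, r0, tx = _comparison_circles(spec)
    s = spec.strength
    # incongruent: the bigger target gets the looser (larger) ring
    ring_t = r0 * (C.DELBOEUF_RING_RATIO + s / 2)
    ring_o = r0 * (C.DELBOEUF_RING_RATIO - s / 2)
    rings = (
        Circle(tx * C.CIRCLE_CENTERS_X, 0.0, ring_t, fill=False),
        Circle(-tx * C.CIRCLE_CENTERS_X, 0.0, ring_o, fill=False),
    )
    return (big, small) + rings


def _measure_delboeuf(plan):
    targets = sorted(plan.targets(), key=lambda c: c.r)
    r0, rbig = targets[0].r, targets[1].r
    d = rbig / r0 - 1.0
    big_sign = math.copysign(1, targets[1].cx)
    ring_t = next(c.r for c in plan.context()
                  if math.copysign(1, c.cx) == big_sign)
    ring_o = next(c.r for c in plan.context()
                  if math.copysign(1, c.cx) != big_sign)
    return d, abs((ring_t - ring_o) / r0)


def _build_ebbinghaus(spec):
    big, small, r0, tx = _comparison_circles(spec)
    s = spec.strength
    # incongruent: the bigger target is surrounded by large circles
    sur_t = r0 * (C.EBBINGHAUS_SURROUND_RATIO + s / 2)
    sur_o = r0 * (C.EBBINGHAUS_SURROUND_RATIO - s / 2)
    prims = [big, small]
    for cx, r in ((tx * C.CIRCLE_CENTERS_X, sur_t),
                  (-tx * C.CIRCLE_CENTERS_X, sur_o)):
        for k in range(C.EBBINGHAUS_N_SURROUND):
            a = 2 * math.pi * k / C.EBBINGHAUS_N_SURROUND
            prims.append(Circle(cx + C.EBBINGHAUS_ORBIT * math.cos(a),
                                C.EBBINGHAUS_ORBIT * math.sin(a), r))
    return tuple(prims)


def _measure_ebbinghaus(plan):
    targets = sorted(plan.targets(), key=lambda c: c.r)
    r0, rbig = targets[0].r, targets[1].r
    d = rbig / r0 - 1.0
    big_sign = math.copysign(1, targets[1].cx)
    sur_t = next(c.r for c in plan.context() if math.copysign(1, c.cx) == big_sign)
    sur_o = next(c.r for c in plan.context() if math.copysign(1, c.cx) != big_sign)
    return d, abs((sur_t - sur_o) / r0)


def _build_rod_frame(spec):
    tdir = _side_sign(spec)
    theta = math.radians(tdir * spec.difficulty)  # rod tilt from vertical
    hx = math.sin(theta) * C.ROD_HALF_LENGTH
    hy = math.cos(theta) * C.ROD_HALF_LENGTH
    rod = Segment(-hx, -hy, hx, hy, role="target")
    # incongruent (s > 0): frame tilted to the rod's side, dragging the
    # perceived vertical with it so the rod appears upright or counter-tilted
    phi = math.radians(tdir * spec.strength)
    h = C.FRAME_HALF_SIZE
    corners = []
    for cxs, cys in ((-h, -h), (h, -h), (h, h), (-h, h)):
        corners.append((cxs * math.cos(phi) - cys * math.sin(phi),
                        cxs * math.sin(phi) + cys * math.cos(phi)))
    frame = tuple(
        Segment(*corners[i], *corners[(i + 1) % 4]) for i in range(4)
    )
    return (rod,) + frame


def _measure_rod_frame(plan):
    rod = plan.targets()[0]
    dx, dy = rod.x2 - rod.x1, rod.y2 - rod.y1
    if dy < 0:
        dx, dy = -dx, -dy
    d = abs(math.degrees(math.atan2(dx, dy)))
    phi = plan.context()[0].angle_deg()
    if phi > 45.0:
        phi -= 90.0
    elif phi <= -45.0:
        phi += 90.0
    return d, abs(phi)


def _build_vertical_horizontal(spec):
    tx = _side_sign(spec)
    lt = C.VH_BASE_LENGTH * (1 + spec.difficulty)
    lo = C.VH_BASE_LENGTH
    s = spec.strength
    # incongruent: the shorter line is rotated toward vertical so it
    # appears longer; congruent: the longer one is
    rotate_longer = s < 0
    segs = []
    for cx, length, is_longer in ((tx * C.VH_CENTERS_X, lt, True),
                                  (-tx * C.VH_CENTERS_X, lo, False)):
        alpha = math.radians(abs(s)) if (is_longer == rotate_longer and s != 0) else 0.0
        hx = math.cos(alpha) * length / 2
        hy = math.sin(alpha) * length / 2
        segs.append(Segment(cx - hx, -hy, cx + hx, hy, role="target"))
    return tuple(segs)


def _measure_vertical_horizontal(plan):
    segs = sorted(plan.targets(), key=lambda p: p.length)
    d = segs[1].length / segs[0].length - 1.0
    angles = [abs(math.degrees(math.atan2(abs(p.y2 - p.y1), abs(p.x2 - p.x1))))
              for p in segs]
    return d, max(angles)


def _build_zollner(spec):
    tdir = _side_sign(spec)
    a_top = math.radians(-tdir * spec.difficulty / 2)
    a_bot = -a_top
    prims = []
    hatch_ts = np.linspace(-C.ZOLLNER_HATCH_SPAN, C.ZOLLNER_HATCH_SPAN,
                           C.ZOLLNER_N_HATCHES)
    for y0, a, hsign in ((C.ZOLLNER_LINE_Y, a_top, 1.0),
                         (-C.ZOLLNER_LINE_Y, a_bot, -1.0)):
        ux, uy = math.cos(a), math.sin(a)
        H = C.ZOLLNER_LINE_HALF
        prims.append(Segment(-H * ux, y0 - H * uy, H * ux, y0 + H * uy,
                             role="target"))
        # hatches rotated away from the line's perpendicular by +-strength,
        # alternating sign between the two lines (classic arrangement);
        # positive strength induces apparent convergence opposite the true one
        hang = a + math.pi / 2 - math.radians(hsign * tdir * spec.strength)
        hx = math.cos(hang) * C.ZOLLNER_HATCH_HALF
        hy = math.sin(hang) * C.ZOLLNER_HATCH_HALF
        for t in hatch_ts:
            cx, cy = t * ux, y0 + t * uy
            prims.append(Segment(cx - hx, cy - hy, cx + hx, cy + hy))
    return tuple(prims)


def _measure_zollner(plan):
    lines = plan.targets()
    top = max(lines, key=lambda p: (p.y1 + p.y2) / 2)
    bot = min(lines, key=lambda p: (p.y1 + p.y2) / 2)
    d = abs(top.angle_deg() - bot.angle_deg())
    hatch = max(plan.context(), key=lambda p: (p.y1 + p.y2) / 2)
    rel = hatch.angle_deg() - (top.angle_deg() + 90.0)
    while rel <= -90.0:
        rel += 180.0
    while rel > 90.0:
        rel -= 180.0
    return d, abs(rel)


def _white_stripe_bounds(k):
    w = 2 * C.WHITE_SPAN_X / C.WHITE_N_STRIPES
    return -C.WHITE_SPAN_X + k * w, -C.WHITE_SPAN_X + (k + 1) * w


def _build_white(spec):
    tx = _side_sign(spec)
    s, d = spec.strength, spec.difficulty
    left_k, right_k = C.WHITE_BAR_STRIPES
    lighter_k = right_k if tx > 0 else left_k
    darker_k = left_k if tx > 0 else right_k
    # incongruent: the lighter bar sits on the light stripe phase, whose
    # coaxial assimilation makes it appear darker
    lighter_phase = lighter_k % 2
    if s > 0:
        phase_gray = {lighter_phase: 0.5 + abs(s) / 2,
                      1 - lighter_phase: 0.5 - abs(s) / 2}
    elif s < 0:
        phase_gray = {lighter_phase: 0.5 - abs(s) / 2,
                      1 - lighter_phase: 0.5 + abs(s) / 2}
    else:
        phase_gray = {0: 0.5, 1: 0.5}
    prims = []
    for k in range(C.WHITE_N_STRIPES):
        x1, x2 = _white_stripe_bounds(k)
        prims.append(Rect(x1, -C.WHITE_SPAN_Y, x2, C.WHITE_SPAN_Y,
                          color=GRAY(phase_gray[k % 2])))
    for k, g in ((lighter_k, 0.5 + d / 2), (darker_k, 0.5 - d / 2)):
        x1, x2 = _white_stripe_bounds(k)
        prims.append(Rect(x1, -C.WHITE_BAR_HALF_HEIGHT, x2,
                          C.WHITE_BAR_HALF_HEIGHT, color=GRAY(g), role="target"))
    return tuple(prims)


def _measure_white(plan):
    grays = sorted(b.color[0] for b in plan.targets())
    d = grays[1] - grays[0]
    stripe_grays = sorted({r.color[0] for r in plan.context()})
    s = stripe_grays[-1] - stripe_grays[0]
    return d, s


def _build_muller_lyer(spec):
    ty = _side_sign(spec)
    lt = C.ML_BASE_LENGTH * (1 + spec.difficulty)
    lo = C.ML_BASE_LENGTH
    s = spec.strength
    phi = math.radians(abs(s))
    prims = []
    for y0, length, is_longer in ((ty * C.ML_LINES_Y, lt, True),
                                  (-ty * C.ML_LINES_Y, lo, False)):
        hl = length / 2
        prims.append(Segment(-hl, y0, hl, y0, role="target"))
        # incongruent: inward fins on the longer (target) line
        inward = (s > 0) == is_longer and s != 0
        for ex in (-hl, hl):
            toward_center = -math.copysign(1.0, ex)
            xdir = toward_center if inward else -toward_center
            fx = xdir * math.sin(phi) * C.ML_FIN_LENGTH
            fy = math.cos(phi) * C.ML_FIN_LENGTH
            prims.append(Segment(ex, y0, ex + fx, y0 + fy))
            prims.append(Segment(ex, y0, ex + fx, y0 - fy))
    return tuple(prims)


def _measure_muller_lyer(plan):
    lines = sorted(plan.targets(), key=lambda p: p.length)
    d = lines[1].length / lines[0].length - 1.0
    fin = plan.context()[0]
    dx, dy = fin.x2 - fin.x1, fin.y2 - fin.y1
    phi = abs(math.degrees(math.atan2(abs(dx), abs(dy))))
    return d, phi


def _build_ponzo(spec):
    ty = _side_sign(spec)
    lt = C.PONZO_BASE_LENGTH * (1 + spec.difficulty)
    lo = C.PONZO_BASE_LENGTH
    s = spec.strength
    # incongruent: the longer bar sits at the diverging end, so the classic
    # convergence-driven expansion inflates the shorter bar instead
    conv = -ty if s > 0 else ty  # +1: flanks converge at the top
    t = math.tan(math.radians(abs(s) / 2))
    X, Y = C.PONZO_FLANK_X, C.PONZO_FLANK_HALF_Y
    # x_left(y) = -X + conv*y*t ; x_right(y) = X - conv*y*t
    flanks = (
        Segment(-X - conv * Y * t, -Y, -X + conv * Y * t, Y),
        Segment(X + conv * Y * t, -Y, X - conv * Y * t, Y),
    )
    bars = (
        Segment(-lt / 2, ty * C.PONZO_BARS_Y, lt / 2, ty * C.PONZO_BARS_Y,
                role="target"),
        Segment(-lo / 2, -ty * C.PONZO_BARS_Y, lo / 2, -ty * C.PONZO_BARS_Y,
                role="target"),
    )
    return bars + flanks


def _measure_ponzo(plan):
    bars = sorted(plan.targets(), key=lambda p: p.length)
    d = bars[1].length / bars[0].length - 1.0
    left = min(plan.context(), key=lambda p: (p.x1 + p.x2) / 2)
    right = max(plan.context(), key=lambda p: (p.x1 + p.x2) / 2)
    s = abs(left.angle_deg() - right.angle_deg())
    if s > 90.0:
        s = 180.0 - s
    return d, s


def _build_poggendorff(spec):
    ty = _side_sign(spec)
    s, d = spec.strength, spec.difficulty
    w = abs(s)
    # ascending obliques appear displaced downward beyond the occluder, so
    # the slope sign puts the classic bias opposite the true offset when
    # the strength is positive (incongruent)
    slope_sign = ty if s == 0 else math.copysign(1.0, s) * ty
    m = slope_sign * C.POGG_SLOPE
    X = C.POGG_X_EXTENT
    entering = Segment(-X, m * (-X + w / 2), -w / 2, 0.0, role="target")
    offset = ty * 2 * d  # difficulty is a fraction of canvas height (2 units)
    y_exit = m * w  # collinear continuation at x = +w/2
    emerging = Segment(w / 2, y_exit + offset, X,
                       m * (X - w / 2) + y_exit + offset, role="target")
    prims = []
    if w > 0:
        prims.append(Rect(-w / 2, -C.POGG_OCCLUDER_HALF_Y, w / 2,
                          C.POGG_OCCLUDER_HALF_Y,
                          color=GRAY(C.POGG_OCCLUDER_GRAY)))
    prims += [entering, emerging]
    return tuple(prims)


def _measure_poggendorff(plan):
    occ = [p for p in plan.context() if isinstance(p, Rect)]
    w = (occ[0].x2 - occ[0].x1) if occ else 0.0
    entering = min(plan.targets(), key=lambda p: (p.x1 + p.x2) / 2)
    emerging = max(plan.targets(), key=lambda p: (p.x1 + p.x2) / 2)
    m = (entering.y2 - entering.y1) / (entering.x2 - entering.x1)
    y_exit = entering.y2 + m * (emerging.x1 - entering.x2)
    delta = emerging.y1 - y_exit
    return abs(delta) / 2, w


def _build_contrast(spec):
    ty = _side_sign(spec)
    s, d = spec.strength, spec.difficulty
    # incongruent: the lighter disc sits on the lighter background half,
    # so simultaneous contrast darkens it
    if s > 0:
        g_target_half, g_other_half = 0.5 + abs(s) / 2, 0.5 - abs(s) / 2
    elif s < 0:
        g_target_half, g_other_half = 0.5 - abs(s) / 2, 0.5 + abs(s) / 2
    else:
        g_target_half = g_other_half = 0.5
    S = C.CONTRAST_SPAN
    top_gray = g_target_half if ty > 0 else g_other_half
    bot_gray = g_other_half if ty > 0 else g_target_half
    halves = (
        Rect(-S, 0.0, S, S, color=GRAY(top_gray)),
        Rect(-S, -S, S, 0.0, color=GRAY(bot_gray)),
    )
    discs = (
        Circle(0.0, ty * C.CONTRAST_DISC_Y, C.CONTRAST_DISC_RADIUS,
               color=GRAY(0.5 + d / 2), role="target"),
        Circle(0.0, -ty * C.CONTRAST_DISC_Y, C.CONTRAST_DISC_RADIUS,
               color=GRAY(0.5 - d / 2), role="target"),
    )
    return halves + discs


def _measure_contrast(plan):
    discs = sorted(plan.targets(), key=lambda c: c.color[0])
    d = discs[1].color[0] - discs[0].color[0]
    halves = sorted(plan.context(), key=lambda r: r.color[0])
    s = halves[1].color[0] - halves[0].color[0]
    return d, s


_BUILDERS = {
    "delboeuf": _build_delboeuf,
    "ebbinghaus": _build_ebbinghaus,
    "rod_frame": _build_rod_frame,
    "vertical_horizontal": _build_vertical_horizontal,
    "zollner": _build_zollner,
    "white": _build_white,
    "muller_lyer": _build_muller_lyer,
    "ponzo": _build_ponzo,
    "poggendorff": _build_poggendorff,
    "contrast": _build_contrast,
}

_MEASURERS = {
    "delboeuf": _measure_delboeuf,
    "ebbinghaus": _measure_ebbinghaus,
    "rod_frame": _measure_rod_frame,
    "vertical_horizontal": _measure_vertical_horizontal,
    "zollner": _measure_zollner,
    "white": _measure_white,
    "muller_lyer": _measure_muller_lyer,
    "ponzo": _measure_ponzo,
    "poggendorff": _measure_poggendorff,
    "contrast": _measure_contrast,
}


def plan_stimulus(spec: StimulusSpec) -> GeometryPlan:
    """Resolve a spec into drawing primitives plus the correct answer."""
    prims = _BUILDERS[spec.illusion_type](spec)
    for p in prims:
        coords = [getattr(p, a) for a in ("x1", "y1", "x2", "y2", "cx", "cy")
                  if hasattr(p, a)]
        if any(abs(c) > 1.0 + 1e-9 for c in coords):
            raise ValueError(
                f"{spec.illusion_type}: primitive leaves the canvas "
                f"(strength/difficulty range misconfigured): {p}"
            )
    return GeometryPlan(primitives=prims,
                        correct_response=spec.target_assignment, spec=spec)


def measure_plan(plan: GeometryPlan) -> tuple:
    """Recover (difficulty, |strength|) from the primitives alone."""
    return _MEASURERS[plan.spec.illusion_type](plan)


def mirror_plan(plan: GeometryPlan) -> list:
    """Reflect all primitives across the response axis.

    Horizontal-axis illusions reflect x -> -x, vertical-axis ones y -> -y.
    Returns the reflected primitive list (no spec attached).
    """
    horizontal = response_axis(plan.spec.illusion_type) == C.HORIZONTAL

    def refl(p):
        if isinstance(p, Segment):
            if horizontal:
                return Segment(-p.x1, p.y1, -p.x2, p.y2, p.width, p.color, p.role)
            return Segment(p.x1, -p.y1, p.x2, -p.y2, p.width, p.color, p.role)
        if isinstance(p, Circle):
            if horizontal:
                return Circle(-p.cx, p.cy, p.r, p.color, p.fill, p.width, p.role)
            return Circle(p.cx, -p.cy, p.r, p.color, p.fill, p.width, p.role)
        if horizontal:
            return Rect(-p.x2, p.y1, -p.x1, p.y2, p.color, p.role)
        return Rect(p.x1, -p.y2, p.x2, -p.y1, p.color, p.role)

    return [refl(p) for p in plan.primitives]
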
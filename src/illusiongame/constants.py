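"""Geometric and design constants for the ten illusions.

All stimulus geometry lives on a normalized square canvas with
x, y in [-1, 1], origin at the centre and y increasing upward.
Angles are in degrees, sizes in canvas units, gray levels in [0, 1].
"""

# ---------------------------------------------------------------------------
# Response axes: which two keys answer each illusion.
# ---------------------------------------------------------------------------
HORIZONTAL = ("left", "right")
VERTICAL = ("up", "down")

RESPONSE_AXIS = {
    "delboeuf": HORIZONTAL,
    "ebbinghaus": HORIZONTAL,
    "rod_frame": HORIZONTAL,
    "vertical_horizontal": HORIZONTAL,
    "zollner": HORIZONTAL,
    "white": HORIZONTAL,
    "muller_lyer": VERTICAL,
    "ponzo": VERTICAL,
    "poggendorff": VERTICAL,
    "contrast": VERTICAL,
}

ILLUSIONS = tuple(RESPONSE_AXIS)

# ---------------------------------------------------------------------------
# Per-illusion parameter ranges (native units).
#
# difficulty: objective target difference, larger = easier.
#   ratio-based illusions: relative difference (bigger/smaller - 1)
#   angle-based: degrees; luminance-based: gray fraction;
#   poggendorff: vertical offset as a fraction of canvas height.
# strength: magnitude of the context manipulation (same unit families).
# ---------------------------------------------------------------------------
DIFFICULTY_RANGE = {
    "delboeuf": (0.05, 0.60),
    "ebbinghaus": (0.05, 0.60),
    "rod_frame": (0.5, 8.0),
    "vertical_horizontal": (0.02, 0.40),
    "zollner": (0.5, 8.0),
    "white": (0.005, 0.30),
    "muller_lyer": (0.02, 0.40),
    "ponzo": (0.02, 0.40),
    "poggendorff": (0.005, 0.12),
    "contrast": (0.005, 0.30),
}

STRENGTH_MAX = {
    "delboeuf": 1.0,     # ring-to-base-target diameter-ratio difference
    "ebbinghaus": 1.0,   # surround-to-base-target diameter-ratio difference
    "rod_frame": 20.0,   # frame tilt, degrees
    "vertical_horizontal": 90.0,  # rotation toward vertical, degrees
    "zollner": 60.0,     # hatch angle from the perpendicular, degrees
    "white": 0.5,        # stripe gray-level separation
    "muller_lyer": 50.0,  # fin angle from the perpendicular, degrees
    "ponzo": 30.0,       # flank convergence angle, degrees
    "poggendorff": 0.6,  # occluder width, canvas units
    "contrast": 0.5,     # background gray-level separation
}

# Non-linear difficulty spacing kind per illusion (pilot-style defaults).
DIFFICULTY_SPACING = {
    "delboeuf": "exponential",
    "ebbinghaus": "exponential",
    "rod_frame": "exponential",
    "vertical_horizontal": "square",
    "zollner": "exponential",
    "white": "cubic",
    "muller_lyer": "square",
    "ponzo": "cubic",
    "poggendorff": "exponential",
    "contrast": "square",
}

# ---------------------------------------------------------------------------
# Geometry defaults (canvas units unless noted).
# ---------------------------------------------------------------------------
TARGET_COLOR = (0.85, 0.1, 0.1)   # red comparison circles (Delboeuf/Ebbinghaus)
LINE_WIDTH = 0.012

CIRCLE_BASE_RADIUS = 0.10         # smaller comparison-circle radius
CIRCLE_CENTERS_X = 0.5            # +- x of the two comparison circles
DELBOEUF_RING_RATIO = 2.4         # ring radius / base target radius, neutral
EBBINGHAUS_SURROUND_RATIO = 1.0   # surround radius / base target radius, neutral
EBBINGHAUS_N_SURROUND = 8
EBBINGHAUS_ORBIT = 0.35           # surround-centre distance from target centre

ROD_HALF_LENGTH = 0.45
FRAME_HALF_SIZE = 0.65

VH_BASE_LENGTH = 0.55             # vertical-horizontal base line length
VH_CENTERS_X = 0.5

ZOLLNER_LINE_HALF = 0.60
ZOLLNER_LINE_Y = 0.30
ZOLLNER_N_HATCHES = 9
ZOLLNER_HATCH_HALF = 0.06
ZOLLNER_HATCH_SPAN = 0.48         # hatch centres span +- this in x

WHITE_N_STRIPES = 10              # even: mirrored bars fall on opposite phases
WHITE_SPAN_X = 0.8
WHITE_SPAN_Y = 0.8
WHITE_BAR_HALF_HEIGHT = 0.25
WHITE_BAR_STRIPES = (3, 6)        # stripe indices hosting the two bars

ML_BASE_LENGTH = 0.55
ML_LINES_Y = 0.30
ML_FIN_LENGTH = 0.18

PONZO_BASE_LENGTH = 0.55
PONZO_BARS_Y = 0.30
PONZO_FLANK_X = 0.50
PONZO_FLANK_HALF_Y = 0.75

POGG_SLOPE = 0.55                 # |dy/dx| of the oblique segment
POGG_X_EXTENT = 0.85
POGG_OCCLUDER_HALF_Y = 0.75
POGG_OCCLUDER_GRAY = 0.2

CONTRAST_DISC_RADIUS = 0.14
CONTRAST_DISC_Y = 0.45
CONTRAST_SPAN = 0.8

# ---------------------------------------------------------------------------
# Study-design defaults
# ---------------------------------------------------------------------------
N_STRENGTH_LEVELS = 15
N_DIFFICULTY_LEVELS = 16
SERIES_SIZES = (56, 72)
N_PRACTICE = 6
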
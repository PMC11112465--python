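"""Named analysis constants.

All thresholds of the stance-curve analysis live here so that the CLI and
pipeline can surface them in one place. Changing any of them is allowed but
is logged by the pipeline as a deviation from the reference analysis.
"""

#: Force threshold separating stance from swing (Newtons). A reading counts
#: as load-bearing only if strictly above this value.
FORCE_THRESHOLD_N: float = 30.0

#: Maximum run of consecutive missing or sub-threshold samples tolerated
#: inside a stance event before the event is terminated.
GAP_TOLERANCE: int = 3

#: Admissible stance duration band, milliseconds (inclusive bounds).
MIN_STANCE_MS: float = 300.0
MAX_STANCE_MS: float = 2000.0

#: Nominal insole recording rate.
NOMINAL_RATE_HZ: float = 100.0

#: Number of equidistant samples of the time-normalized stance curve
#: (one per percent of stance duration).
N_POINTS: int = 100

#: Gaussian smoothing used only for extremum localization.
GAUSSIAN_SIGMA: float = 3.0
GAUSSIAN_KERNEL_SIZE: int = 7

#: Extremum candidates within the first/last EDGE_MARGIN indices are
#: implausible in time (cascade strategy 1).
EDGE_MARGIN: int = 10

#: Same-polarity candidates within POOL_SPAN indices of each other form one
#: pool (cascade strategy 2).
POOL_SPAN: int = 5

#: Span of the strict-monotony check on either side of a candidate
#: (cascade strategies 3 and 4).
MONOTONY_SPAN: int = 5

#: Fraction of the peak force defining the loading/unloading slope crossings.
CROSSING_FRACTION: float = 0.8

#: Standard gravity used to convert Newtons to body-weight fractions.
GRAVITY_MS2: float = 9.81

#: Treadmill grades of the reference protocol, percent.
GRADES: tuple[int, ...] = (-20, -15, -10, -5, 0, 5, 10, 15, 20)

#: Canonical order of the nine stance-curve parameters.
PARAMETER_NAMES: tuple[str, ...] = (
    "fz2",
    "fz3",
    "fz4",
    "fmean_stance",
    "fmean_load",
    "fmean_mid",
    "fmean_unload",
    "loading_slope",
    "unloading_slope",
)
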
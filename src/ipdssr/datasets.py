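"""Embedded worked datasets: jute-fibre breaking strengths and electrical
insulation failure times, with their PFFC sub-samples.

Both datasets are classical strength/stress pairs.  The jute data are
breaking strengths of fibres at gauge lengths 15 mm (strength, X) and 20 mm
(stress, Y), each divided by 10; the insulation data are failure times of two
insulation types under continuously increasing voltage stress, each
multiplied by 10.  For each pair, four prefixed censoring schemes with their
progressively first-failure censored sub-samples are stored exactly as
published — including the known internal inconsistencies of the jute
sub-samples (a few values appear there that are absent from the published
first-failure lists); nothing is "corrected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import CensoringScheme, PFFCSample

__all__ = ["DatasetFixture", "load_fixture", "available_fixtures"]


@dataclass(frozen=True)
class DatasetFixture:
    name: str
    x_full: np.ndarray  # complete strength sample
    y_full: np.ndarray  # complete stress sample
    schemes: dict[int, CensoringScheme]
    x_pffc: dict[int, PFFCSample]
    y_pffc: dict[int, PFFCSample]
    x_first_failure: np.ndarray | None = None
    y_first_failure: np.ndarray | None = None


_JUTE_X = [
    59.440, 20.275, 16.837, 57.486, 22.565, 7.638, 15.667, 12.781, 81.387,
    56.239, 46.847, 13.509, 7.224, 49.794, 35.556, 56.907, 64.048, 20.042,
    55.042, 74.875, 48.966, 67.806, 45.771, 10.673, 71.630, 4.266, 8.040,
    33.922, 7.009, 19.342,
]
_JUTE_Y = [
    7.146, 41.902, 28.464, 58.557, 45.660, 11.385, 18.785, 68.816, 66.266,
    4.558, 57.862, 75.670, 59.429, 16.649, 9.972, 70.736, 76.514, 18.713,
    14.596, 35.070, 54.744, 11.699, 37.581, 58.160, 11.986, 4.801, 20.016,
    3.675, 24.453, 8.355,
]
_JUTE_X_FF = [
    4.266, 7.009, 7.224, 8.040, 10.673, 13.509, 15.667, 16.837, 19.342,
    20.042, 20.275, 45.771, 46.847, 49.794, 56.239,
]
_JUTE_Y_FF = [
    3.675, 4.558, 4.801, 8.355, 9.972, 11.699, 14.596, 18.713, 18.785,
    20.016, 24.453, 28.464, 37.581, 54.744, 59.429,
]
_JUTE_SCHEMES = {
    1: (2, [5, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
    2: (2, [1, 0, 0, 1, 0, 0, 2, 0, 0, 1]),
    3: (2, [0, 0, 0, 0, 0, 0, 0, 0, 0, 5]),
    4: (2, [0] * 15),
}
_JUTE_X_PFFC = {
    1: [4.266, 12.781, 13.509, 16.837, 19.342, 20.042, 22.565, 46.847, 57.486, 71.630],
    2: [4.266, 7.224, 7.638, 8.040, 12.781, 13.509, 16.837, 22.565, 46.847, 48.966],
    3: [4.266, 7.009, 7.224, 7.638, 8.040, 12.781, 13.509, 16.837, 19.342, 20.275],
    4: [4.266, 7.009, 7.224, 7.638, 8.040, 10.673, 12.781, 13.509, 15.667,
        19.342, 20.042, 22.565, 46.847, 49.794, 64.048],
}
_JUTE_Y_PFFC = {
    1: [3.675, 11.385, 11.699, 11.986, 16.649, 24.453, 28.464, 45.660, 58.160, 59.429],
    2: [3.675, 4.801, 7.146, 8.355, 11.385, 11.986, 14.596, 24.453, 28.464, 37.581],
    3: [3.675, 4.558, 4.801, 7.146, 9.972, 11.385, 11.699, 11.986, 16.649, 20.016],
    4: [3.675, 4.558, 4.801, 8.355, 9.972, 11.385, 11.986, 16.649, 18.713,
        18.785, 24.453, 35.070, 41.902, 57.862, 66.266],
}

_INS_X = [
    0.97, 0.14, 0.3, 1.34, 2.4, 0.84, 1.46, 0.24, 0.45, 0.04, 0.99, 2.77,
    4.72, 0.94, 0.23, 1.46, 0.3, 0.31, 1.04, 1.05, 0.36, 0.65, 0.22, 0.98,
    1.78, 0.59, 0.14, 0.07, 0.07, 2.86,
]
_INS_Y = [
    1.99, 2.52, 1.03, 4.55, 1.35, 3.48, 3.21, 1.66, 0.4, 0.27, 5.19, 2.7,
    0.08, 0.3, 0.84, 2.36, 3.15, 1.77, 2.68, 1.8, 7.96, 2.45, 7.03, 0.45,
    0.17, 8.21, 9.42, 3.14, 2.81, 6.52,
]
_INS_SCHEMES = {
    1: (3, [2, 0, 0, 0, 0, 0, 0, 0]),
    2: (3, [1, 0, 0, 0, 0, 0, 0, 1]),
    3: (3, [0, 0, 0, 0, 0, 0, 0, 2]),
    4: (3, [0] * 10),
}
_INS_X_PFFC = {
    1: [0.04, 0.22, 0.23, 0.30, 0.30, 0.36, 0.59, 0.65],
    2: [0.04, 0.14, 0.22, 0.23, 0.24, 0.31, 0.45, 0.97],
    3: [0.04, 0.07, 0.07, 0.14, 0.14, 0.23, 0.31, 0.45],
    4: [0.04, 0.07, 0.07, 0.14, 0.14, 0.22, 0.23, 0.24, 0.30, 0.45],
}
_INS_Y_PFFC = {
    1: [0.08, 0.30, 0.40, 0.45, 0.84, 1.03, 2.68, 3.15],
    2: [0.08, 0.27, 0.40, 0.84, 1.03, 1.35, 1.66, 2.68],
    3: [0.08, 0.17, 0.27, 0.30, 0.84, 1.03, 1.66, 1.80],
    4: [0.08, 0.17, 0.27, 0.30, 0.40, 0.45, 1.35, 2.36, 2.52, 2.68],
}


def _build(name, x_full, y_full, schemes, x_pffc, y_pffc, x_ff=None, y_ff=None):
    built_schemes = {
        cs: CensoringScheme(
            n_groups=len(G) + sum(G), k_per_group=k, m_failures=len(G),
            removals=tuple(G),
        )
        for cs, (k, G) in schemes.items()
    }
    return DatasetFixture(
        name=name,
        x_full=np.asarray(x_full),
        y_full=np.asarray(y_full),
        schemes=built_schemes,
        x_pffc={cs: PFFCSample(np.asarray(v), built_schemes[cs]) for cs, v in x_pffc.items()},
        y_pffc={cs: PFFCSample(np.asarray(v), built_schemes[cs]) for cs, v in y_pffc.items()},
        x_first_failure=None if x_ff is None else np.asarray(x_ff),
        y_first_failure=None if y_ff is None else np.asarray(y_ff),
    )


def available_fixtures() -> list[str]:
    return ["jute", "insulation"]


def load_fixture(name: str) -> DatasetFixture:
    """Return the named embedded dataset ("jute" or "insulation")."""
    if name == "jute":
        return _build("jute", _JUTE_X, _JUTE_Y, _JUTE_SCHEMES, _JUTE_X_PFFC,
                      _JUTE_Y_PFFC, _JUTE_X_FF, _JUTE_Y_FF)
    if name == "insulation":
        return _build("insulation", _INS_X, _INS_Y, _INS_SCHEMES, _INS_X_PFFC,
                      _INS_Y_PFFC)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
    )
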
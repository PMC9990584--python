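"""Built-in datasets: aircraft air-conditioning failure gaps and a JPC record.

The two lifetime vectors are the classic inter-failure times (hours)
between air-conditioning system failures of Boeing 720 jets, planes 7914
(24 gaps) and 7913 (27 gaps).  The joint progressively censored record
``jpc_application`` combines the two planes (m = 24, n = 27, r = 10).

The published JPC record is shipped exactly as printed even though it
fails its own counting identities (sum(R) = 38 differs from
m + n - r = 41 and sum(S) = 18 from m - m_r = 17); loading it attaches
the corresponding validation warnings rather than repairing the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .jpc_scheme import CensoringScheme, JPCSample, Violation, validate

__all__ = ["Fixture", "PLANE_7914", "PLANE_7913", "FIXTURE_NAMES", "load_fixture"]

PLANE_7914 = (
    3, 5, 5, 13, 14, 15, 22, 22, 23, 30, 36, 39, 44, 46, 50, 72, 79, 88,
    97, 102, 139, 188, 197, 210,
)

PLANE_7913 = (
    1, 4, 11, 16, 18, 18, 18, 24, 31, 39, 46, 51, 54, 63, 68, 77, 80, 82,
    97, 106, 111, 141, 142, 163, 191, 206, 216,
)

_JPC_LAM = (2.2, 3.3, 3.4, 3.4, 3.5, 3.6, 3.7, 3.8, 3.8, 3.8)
_JPC_H = (1, 0, 1, 1, 0, 1, 0, 1, 1, 1)
_JPC_S = (5, 0, 0, 0, 5, 0, 0, 0, 0, 8)
_JPC_T = (5, 0, 0, 0, 5, 0, 0, 0, 0, 10)
_JPC_R = (10, 0, 0, 0, 10, 0, 0, 0, 0, 18)

FIXTURE_NAMES = ("plane7914", "plane7913", "jpc_application")


@dataclass(frozen=True)
class Fixture:
    """An immutable named dataset with provenance and validation notes."""

    name: str
    payload: object  # lifetime array, or (JPCSample, CensoringScheme)
    note: str
    warnings: tuple[Violation, ...] = ()


def load_fixture(name: str) -> Fixture:
    """Return one of the built-in datasets by name.

    Known names: ``plane7914``, ``plane7913`` (lifetime vectors) and
    ``jpc_application`` (a (JPCSample, CensoringScheme) pair with its
    validation warnings attached).
    """
    if name == "plane7914":
        return Fixture(
            name=name,
            payload=np.array(PLANE_7914, dtype=float),
            note="hours between air-conditioning failures, Boeing 720 plane 7914 (24 gaps)",
        )
    if name == "plane7913":
        return Fixture(
            name=name,
            payload=np.array(PLANE_7913, dtype=float),
            note="hours between air-conditioning failures, Boeing 720 plane 7913 (27 gaps)",
        )
    if name == "jpc_application":
        # r = 10 but the printed removal plan sums to 38, not K - r = 41;
        # CensoringScheme would reject it, so the scheme is assembled
        # field-by-field without the constructor checks.
        scheme = object.__new__(CensoringScheme)
        object.__setattr__(scheme, "m", 24)
        object.__setattr__(scheme, "n", 27)
        object.__setattr__(scheme, "r", 10)
        object.__setattr__(scheme, "R", _JPC_R)
        sample = JPCSample(
            lam=np.array(_JPC_LAM), h=np.array(_JPC_H),
            s=np.array(_JPC_S), t=np.array(_JPC_T),
        )
        return Fixture(
            name=name,
            payload=(sample, scheme),
            note=("joint progressively censored record combining planes 7914 (pop 1) "
                  "and 7913 (pop 2); shipped as printed, counting identities violated"),
            warnings=tuple(validate(sample, scheme)),
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
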
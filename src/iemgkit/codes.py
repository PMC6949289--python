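"""Movement-code semantics of the recording protocol.

Each protocol stage carries a base code ``base.substage`` (e.g. 3.1 for the
ring-finger MVC-flexion sub-stage).  Stages driven by a go cue (the MVC and
synergy stages) add a third digit: ``x.x1`` while the cue is on and ``x.x0``
during the rest/preparation period inside the sub-stage.  Tracking stages
(sine, circle, trumpet) keep the plain two-digit code for their whole
duration, so the cue/rest distinction does not apply to them.

Codes are compared at two-decimal precision.  Internally they are held as
integers scaled by 100 (311 for 3.11) because 0.01 increments are not exactly
representable in binary floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import pandas as pd

from .errors import UnknownCodeError

__all__ = [
    "CueState",
    "MovementCode",
    "decode_code",
    "encode_code",
    "code_to_int",
    "int_to_code",
    "movement_table",
    "iter_codes",
    "stage_kind",
]


class CueState(Enum):
    """Tri-state cue flag of a decoded movement code."""

    CUE = "cue"
    REST = "rest"
    NOT_APPLICABLE = "n/a"


#: stage kinds; "mvc" and "synergy" sub-stages carry the x.x0/x.x1 cue digit
_MVC, _SINE, _CIRCLE, _TRUMPET, _SYNERGY = "mvc", "sine", "circle", "trumpet", "synergy"

_FINGERS = ["Index finger", "Middle finger", "Ring finger", "Little finger"]

# (base, substage, description, kind) in protocol order
_STAGES: list[tuple[int, int, str, str]] = []
for _i, _f in enumerate(_FINGERS, start=1):
    _STAGES += [
        (_i, 1, f"{_f}: MVC Flexion", _MVC),
        (_i, 2, f"{_f}: MVC Extension", _MVC),
        (_i, 3, f"{_f}: Track sine cue", _SINE),
    ]
_STAGES += [
    (5, 1, "Thumb: MVC Flexion", _MVC),
    (5, 2, "Thumb: MVC Extension", _MVC),
    (5, 3, "Thumb: Track sine cue", _SINE),
    (6, 1, "Thumb: MVC Adduction", _MVC),
    (6, 2, "Thumb: MVC Abduction", _MVC),
    (6, 3, "Thumb: Track sine cue (add-abd)", _SINE),
    (7, 1, "Wrist: MVC Flexion", _MVC),
    (7, 2, "Wrist: MVC Extension", _MVC),
    (7, 3, "Wrist: Track sine cue", _SINE),
    (8, 1, "Wrist: MVC Supination", _MVC),
    (8, 2, "Wrist: MVC Pronation", _MVC),
    (8, 3, "Wrist: Track sine cue (sup-pro)", _SINE),
    (9, 1, "Thumb joystick: Track circular cue", _CIRCLE),
    (10, 1, "Wrist joystick: Track circular cue", _CIRCLE),
    (11, 1, "Touch index finger with the thumb: Track sine cue", _TRUMPET),
    (12, 1, "Touch middle finger with the thumb: Track sine cue", _TRUMPET),
    (13, 1, "Touch ring finger with the thumb: Track sine cue", _TRUMPET),
    (14, 1, "Touch little finger with the thumb: Track sine cue", _TRUMPET),
    (15, 1, "All fingers flexion (without thumb): 4 repetitions", _SYNERGY),
    (16, 1, "All fingers extension: 4 repetitions", _SYNERGY),
    (17, 1, "Palmar grasp: 4 repetitions", _SYNERGY),
    (18, 1, "Pronation followed by Palmar grasp: 4 repetitions", _SYNERGY),
    (19, 1, "Pointing: index-extend, digits 3-5 flex: 4 repetitions", _SYNERGY),
    (20, 1, "3-digit pinch: 4 repetitions", _SYNERGY),
    (21, 1, "3-digit pinch with pronation: 4 repetitions", _SYNERGY),
    (22, 1, "Key grasp followed with pronation: 4 repetitions", _SYNERGY),
]

# (base, substage) -> (description, kind)
_TABLE: dict[tuple[int, int], tuple[str, str]] = {
    (b, s): (d, k) for b, s, d, k in _STAGES
}

#: kinds whose sub-stages carry the trailing cue/rest digit
_CUE_CAPABLE = {_MVC, _SYNERGY}


@dataclass(frozen=True)
class MovementCode:
    """A decoded protocol movement code."""

    base: int
    substage: int
    cue_active: CueState
    description: str
    kind: str

    @property
    def code(self) -> float:
        """The two-decimal float encoding used in the published files."""
        return code_to_int(self) / 100.0


def stage_kind(base: int, substage: int) -> str:
    """Return the stage kind ('mvc', 'sine', 'circle', 'trumpet', 'synergy')."""
    try:
        return _TABLE[(base, substage)][1]
    except KeyError:
        raise UnknownCodeError(f"no protocol stage {base}.{substage}") from None


def code_to_int(mc: MovementCode) -> int:
    """Scale a MovementCode to the internal 100x integer encoding."""
    val = mc.base * 100 + mc.substage * 10
    if mc.cue_active is CueState.CUE:
        val += 1
    return val


def int_to_code(val: int) -> MovementCode:
    """Decode the internal 100x integer encoding."""
    base, rem = divmod(int(val), 100)
    substage, digit = divmod(rem, 10)
    key = (base, substage)
    if key not in _TABLE:
        raise UnknownCodeError(f"unknown movement code {val / 100:.2f}")
    description, kind = _TABLE[key]
    if kind in _CUE_CAPABLE:
        cue = CueState.CUE if digit == 1 else CueState.REST
        if digit > 1:
            raise UnknownCodeError(f"invalid cue digit in code {val / 100:.2f}")
    else:
        if digit != 0:
            raise UnknownCodeError(
                f"tracking stage {base}.{substage} takes no cue digit "
                f"(got {val / 100:.2f})"
            )
        cue = CueState.NOT_APPLICABLE
    return MovementCode(base, substage, cue, description, kind)


def decode_code(code: float) -> MovementCode:
    """Decode a two-decimal movement code (e.g. 3.11, 20.10, 4.3).

    Raises :class:`~iemgkit.errors.UnknownCodeError` for codes outside the
    protocol table.
    """
    return int_to_code(round(float(code) * 100))


def encode_code(base: int, substage: int, cue: bool | None = None) -> float:
    """Encode a stage as its two-decimal code.

    ``cue`` must be given for MVC/synergy sub-stages and omitted (or None)
    for tracking sub-stages.
    """
    kind = stage_kind(base, substage)
    if kind in _CUE_CAPABLE:
        if cue is None:
            raise UnknownCodeError(
                f"stage {base}.{substage} needs an explicit cue/rest flag"
            )
        state = CueState.CUE if cue else CueState.REST
    else:
        if cue is not None:
            raise UnknownCodeError(
                f"tracking stage {base}.{substage} takes no cue flag"
            )
        state = CueState.NOT_APPLICABLE
    mc = MovementCode(base, substage, state, *_TABLE[(base, substage)])
    return code_to_int(mc) / 100.0


def iter_codes() -> Iterator[MovementCode]:
    """Iterate every valid movement code (both cue states where applicable)."""
    for (base, sub), (desc, kind) in _TABLE.items():
        if kind in _CUE_CAPABLE:
            yield MovementCode(base, sub, CueState.REST, desc, kind)
            yield MovementCode(base, sub, CueState.CUE, desc, kind)
        else:
            yield MovementCode(base, sub, CueState.NOT_APPLICABLE, desc, kind)


def movement_table() -> pd.DataFrame:
    """The protocol movement table as a (code, description) DataFrame.

    Base sub-stage codes only (1.1 ... 22.1), in protocol order, mirroring the
    ``.Movements`` element of the published session files.
    """
    return pd.DataFrame(
        [(b + s / 10.0, d) for b, s, d, _ in _STAGES],
        columns=["code", "description"],
    )
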
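"""Acquisition protocol presets.

Three protocols drive the simulations, mirroring a 3 T cell-tracking
study design:

* ``cones_ute`` — five-echo UTE acquisition (center-out trajectory family)
  with a first echo of 0.03 ms, short enough to catch bone and
  SPIO-laden tissue before their signal has decayed.
* ``cartesian_mge`` — six-echo Cartesian multi-echo gradient echo whose
  first echo at 7 ms misses short-T2* species entirely.
* ``fse_r2`` — four-echo fast-spin-echo series for R2 (as opposed to R2*)
  mapping; spin echoes refocus static dephasing, so this mode ignores
  the susceptibility field.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Protocol:
    name: str
    echo_times: tuple[float, ...]  # ms
    tr: float  # ms
    flip_angle: float  # degrees
    mode: str  # "r2star" (gradient echo) or "r2" (spin echo)

    def __post_init__(self) -> None:
        if self.mode not in ("r2star", "r2"):
            raise ValueError(f"unknown mode {self.mode!r}")
        tes = self.echo_times
        if len(tes) < 2 or any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo_times must be strictly increasing with >= 2 echoes")
        if self.mode == "r2star" and tes[-1] >= self.tr:
            raise ValueError("gradient-echo echo times must all be below TR")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


CONES_UTE = Protocol(
    name="cones_ute",
    echo_times=(0.03, 4.0, 8.1, 12.1, 16.1),
    tr=23.0,
    flip_angle=15.0,
    mode="r2star",
)

CARTESIAN_MGE = Protocol(
    name="cartesian_mge",
    echo_times=(7.0, 12.8, 18.5, 24.3, 30.1, 35.8),
    tr=40.7,
    flip_angle=20.0,
    mode="r2star",
)

FSE_R2 = Protocol(
    name="fse_r2",
    echo_times=(2.8, 31.7, 63.8, 112.0),
    tr=1920.0,
    flip_angle=20.0,
    mode="r2",
)

PROTOCOLS: dict[str, Protocol] = {
    p.name: p for p in (CONES_UTE, CARTESIAN_MGE, FSE_R2)
}


def get_protocol(name: str) -> Protocol:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        ) from None
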
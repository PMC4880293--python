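"""Emission model: from hidden dyad states to sequenced read pairs.

After (oxidative) bisulfite treatment and sequencing, each strand of a dyad
is read as T or C.  Ideal chemistry maps, under plain bisulfite (BS),
``u -> T`` and ``m, h -> C``; under oxidative bisulfite (oxBS), ``u, h -> T``
and ``m -> C``.  Real conversions fail at small rates, parameterised by the
success probabilities estimated from control cytosines in the hairpin
linker:

* ``c`` — an unmodified C is converted (read T),
* ``d`` — a 5mC is retained (read C),
* ``e`` — a 5hmC is retained as C under BS,
* ``f`` — a 5hmC is converted to T under oxBS.

The observable states are the read pairs in canonical order TT, TC, CT, CC
(upper strand first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import LOWER_MARK, UPPER_MARK, validate_distribution

#: Canonical ordering of the observable read-pair states.
OBS_STATES: tuple[str, ...] = ("TT", "TC", "CT", "CC")

OBS_INDEX: dict[str, int] = {s: i for i, s in enumerate(OBS_STATES)}

#: Observable-state permutation induced by exchanging the strands.
OBS_SWAP: np.ndarray = np.array([OBS_INDEX[s[1] + s[0]] for s in OBS_STATES])

TREATMENTS = ("bs", "ox")


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")
    return value


@dataclass
class ConversionProfile:
    """Conversion success probabilities of one treatment at one timepoint.

    ``e`` is required for BS profiles, ``f`` for oxBS profiles; the unused
    field may stay ``None``.  Profiles may differ between treatments and
    across observation days.
    """

    treatment: str
    c: float = 1.0
    d: float = 1.0
    e: float | None = None
    f: float | None = None
    day: int | None = None
    locus: str | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        _check_prob("c", self.c)
        _check_prob("d", self.d)
        if self.treatment == "bs":
            if self.e is None:
                raise ValueError("BS profile requires e (5hmC retention probability)")
            _check_prob("e", self.e)
        else:
            if self.f is None:
                raise ValueError("oxBS profile requires f (5hmC conversion probability)")
            _check_prob("f", self.f)

    @property
    def e_or_f(self) -> float:
        return self.e if self.treatment == "bs" else self.f  # type: ignore[return-value]


def perfect_profile(treatment: str, day: int | None = None) -> ConversionProfile:
    """Error-free conversion profile (c = d = e = f = 1)."""
    if treatment == "bs":
        return ConversionProfile("bs", c=1.0, d=1.0, e=1.0, day=day)
    return ConversionProfile("ox", c=1.0, d=1.0, f=1.0, day=day)


def strand_emission(mark: str, profile: ConversionProfile) -> np.ndarray:
    """Read distribution ``[P(T), P(C)]`` of a single strand with the given mark."""
    if mark not in ("u", "m", "h"):
        raise ValueError(f"unknown strand mark {mark!r}")
    if mark == "u":
        return np.array([profile.c, 1.0 - profile.c])
    if mark == "m":
        return np.array([1.0 - profile.d, profile.d])
    if profile.treatment == "bs":
        return np.array([1.0 - profile.e, profile.e])
    return np.array([profile.f, 1.0 - profile.f])


def emission_matrix(profile: ConversionProfile) -> np.ndarray:
    """9x4 matrix mapping hidden dyad states to read-pair probabilities.

    The two strands are read through independent channels, so each entry is
    the product of the per-strand emission probabilities.
    """
    E = np.empty((9, 4))
    for i, (up, lo) in enumerate(zip(UPPER_MARK, LOWER_MARK)):
        pu = strand_emission(up, profile)  # [T, C]
        pl = strand_emission(lo, profile)
        E[i] = [pu[0] * pl[0], pu[0] * pl[1], pu[1] * pl[0], pu[1] * pl[1]]
    return E


def observable_distribution(pi: np.ndarray, profile: ConversionProfile) -> np.ndarray:
    """Distribution over TT/TC/CT/CC implied by hidden distribution ``pi``."""
    return validate_distribution(pi) @ emission_matrix(profile)


def estimate_conversion_errors(
    treatment: str,
    c_control: tuple[int, int],
    mc_control: tuple[int, int],
    hmc_control: tuple[int, int],
    day: int | None = None,
    locus: str | None = None,
) -> ConversionProfile:
    """Estimate a conversion profile from hairpin-linker control counts.

    Each argument is ``(n_failed, n_total)`` for one control base type: the
    number of bases that failed their intended transformation (an unmodified
    C read as C, a 5mC read as T, a 5hmC read as T under BS or as C under
    oxBS) out of all analysed controls of that type.  The error rate is the
    plain ratio failed/total; the profile stores the complementary success
    probabilities.
    """

    def rate(name: str, failed: int, total: int) -> float:
        if total <= 0:
            raise ValueError(f"no {name} control bases: total must be > 0")
        if not 0 <= failed <= total:
            raise ValueError(f"{name} control: failed={failed} outside [0, {total}]")
        return failed / total

    c = 1.0 - rate("C", *c_control)
    d = 1.0 - rate("5mC", *mc_control)
    s = 1.0 - rate("5hmC", *hmc_control)
    if treatment == "bs":
        return ConversionProfile("bs", c=c, d=d, e=s, day=day, locus=locus)
    return ConversionProfile("ox", c=c, d=d, f=s, day=day, locus=locus)
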
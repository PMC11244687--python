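"""Random-draw primitives for uncertainty sources.

Two sampling laws are supported: an (untruncated) normal distribution and a
bounded uniform distribution.  For a uniform distribution on
``[center - a, center + a]`` the standard deviation is ``a / sqrt(3)``;
draws never leave the bounds.  Each uncertainty source draws from its own
labelled, statistically independent sub-stream of a single run seed, so
adding or zeroing one source never perturbs another source's sequence.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

_SQRT3 = math.sqrt(3.0)


def uniform_sigma(half_width: float) -> float:
    """Standard deviation of a uniform distribution of given half-width.

    ``sigma = half_width / sqrt(3)`` (a uniform on ``[x-, x+]`` has
    ``sigma = (x+ - x-) / (2 sqrt(3))``).
    """
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    return half_width / _SQRT3


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling law of one uncertainty source.

    Parameters
    ----------
    kind : {"normal", "uniform"}
        Normal draws are untruncated; uniform draws are hard-bounded at
        ``center +/- half_width``.
    sigma : float
        Standard deviation.  For percent-valued sources this is a relative
        fraction (0.004 for 0.4 %); for physical sources it carries the
        declared unit (cm, degC, mbar).
    half_width : float or None
        Uniform only.  May be given instead of (or as well as) ``sigma``;
        whichever is missing is derived via ``sigma = half_width / sqrt(3)``.
        Supplying both inconsistently is a configuration error.
    center : float
        Offset added to every draw (default 0).
    """

    kind: str
    sigma: float | None = None
    half_width: float | None = None
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "normal":
            if self.sigma is None:
                raise ValueError("normal spec requires sigma")
            if self.half_width is not None:
                raise ValueError("normal spec is untruncated; half_width not allowed")
        else:
            sigma, hw = self.sigma, self.half_width
            if sigma is None and hw is None:
                raise ValueError("uniform spec requires sigma or half_width")
            if hw is None:
                hw = sigma * _SQRT3
                object.__setattr__(self, "half_width", hw)
            elif sigma is None:
                object.__setattr__(self, "sigma", uniform_sigma(hw))
            else:
                expect = uniform_sigma(hw)
                scale = max(abs(expect), abs(sigma), 1e-300)
                if abs(expect - sigma) > 1e-12 * scale:
                    raise ValueError(
                        f"inconsistent uniform spec: sigma={sigma} vs "
                        f"half_width/sqrt(3)={expect}"
                    )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.half_width is not None and self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    def scaled(self, factor: float) -> "DistributionSpec":
        """Spec with sigma (and half_width) multiplied by ``factor``."""
        if self.kind == "uniform":
            return DistributionSpec("uniform", half_width=self.half_width * factor,
                                    center=self.center)
        return DistributionSpec("normal", sigma=self.sigma * factor, center=self.center)


def _label_entropy(label: str) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


@dataclass
class RandomStream:
    """A run seed fanned out into independent labelled sub-streams.

    Identical ``(seed, label)`` pairs reproduce identical draw sequences;
    distinct labels give statistically independent generators.
    """

    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    def generator(self, label: str) -> np.random.Generator:
        if label not in self._cache:
            ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, _label_entropy(label)])
            self._cache[label] = np.random.default_rng(ss)
        return self._cache[label]


def draw(spec: DistributionSpec, count: int, stream: RandomStream, label: str) -> np.ndarray:
    """Draw ``count`` i.i.d. values from ``spec`` on the sub-stream ``label``."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = stream.generator(label)
    if spec.kind == "normal":
        if spec.sigma == 0.0:
            return np.full(count, spec.center)
        return spec.center + spec.sigma * rng.standard_normal(count)
    if spec.half_width == 0.0:
        return np.full(count, spec.center)
    return rng.uniform(spec.center - spec.half_width, spec.center + spec.half_width, count)


def temperature_draw(
    T0: float,
    specA: DistributionSpec,
    specB: DistributionSpec,
    stream: RandomStream,
    count: int = 1,
) -> np.ndarray:
    """Water temperature with Type A (normal) and Type B (uniform) components.

    ``T_i = T0 + dT_A,i + dT_B,i`` with the two perturbations drawn
    independently: the Type A term reflects observed thermometer-to-thermometer
    scatter, the Type B term the manufacturer's stated accuracy converted to a
    bounded uniform law.
    """
    a = draw(specA, count, stream, "temperature_A")
    b = draw(specB, count, stream, "temperature_B")
    return T0 + a + b
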
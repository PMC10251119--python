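"""Park-Miller "minimal standard" pseudorandom number generator.

The simulator's only sources of randomness are the biomass split and the
division direction drawn at each cell division.  Both are driven by this
multiplicative congruential generator (a = 16807, m = 2**31 - 1) so that a
run is a pure function of its integer seed: re-running with the same seed
replays exactly the same sequence of "luck".  Draws are consumed in a fixed,
documented order (split fraction first, then the two direction deviates) so
seeds are portable across implementations.
"""

from __future__ import annotations

import math

MULTIPLIER = 16807
MODULUS = 2**31 - 1  # Mersenne prime 2147483647


class InvalidSeedError(ValueError):
    """Seed/state outside the generator's period [1, 2**31 - 2]."""


def park_miller_next(state: int) -> tuple[int, float]:
    """Advance the minimal-standard recurrence one step.

    Parameters
    ----------
    state
        Current generator state, an integer in ``[1, 2**31 - 2]``.

    Returns
    -------
    (new_state, deviate)
        ``new_state = (16807 * state) mod (2**31 - 1)`` and the uniform
        deviate ``new_state / (2**31 - 1)``, which lies strictly in (0, 1).
    """
    if not isinstance(state, (int,)) or isinstance(state, bool):
        raise InvalidSeedError(f"state must be an integer, got {state!r}")
    if state < 1 or state > MODULUS - 1:
        raise InvalidSeedError(
            f"state must be in [1, {MODULUS - 1}], got {state}"
        )
    new_state = (MULTIPLIER * state) % MODULUS
    return new_state, new_state / MODULUS


class ParkMiller:
    """Stateful stream wrapper around :func:`park_miller_next`.

    One stream is used per simulation run.  Helper draws below document the
    exact number of deviates each consumes.
    """

    def __init__(self, seed: int):
        if not isinstance(seed, int) or isinstance(seed, bool):
            raise InvalidSeedError(f"seed must be an integer, got {seed!r}")
        if seed < 1 or seed > MODULUS - 1:
            raise InvalidSeedError(f"seed must be in [1, {MODULUS - 1}], got {seed}")
        self.state = seed

    def uniform(self) -> float:
        """One deviate, uniform in (0, 1). Consumes 1 draw."""
        self.state, u = park_miller_next(self.state)
        return u

    def split_fraction(self, low: float = 0.4, high: float = 0.6) -> float:
        """Biomass fraction for the first daughter, U(low, high). 1 draw."""
        return low + (high - low) * self.uniform()

    def unit_vector(self) -> tuple[float, float, float]:
        """Direction uniform on the unit sphere. Consumes exactly 2 draws.

        Inverse-transform sampling (cos-theta uniform in [-1, 1], azimuth
        uniform in [0, 2pi)) is used instead of rejection so the number of
        draws per division is fixed and seed streams stay portable.
        """
        z = 2.0 * self.uniform() - 1.0
        phi = 2.0 * math.pi * self.uniform()
        r = math.sqrt(max(0.0, 1.0 - z * z))
        return r * math.cos(phi), r * math.sin(phi), z
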
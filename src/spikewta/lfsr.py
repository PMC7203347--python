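"""4-bit linear feedback shift register and sparse noise frames.

The spiking layer needs an uncorrelated background signal: frames with a
single ON cell drawn pseudo-randomly over the 4x4 input field.  A Fibonacci
LFSR over GF(2) with the maximal-length polynomial x^4 + x^3 + 1 supplies the
cell index; its orbit visits all 15 non-zero register values before
repeating, so the noise is deterministic, replayable and (over one period)
nearly uniform over the field.
"""

from __future__ import annotations

import numpy as np

FIELD_SIZE = 16
MAXIMAL_TAPS = (4, 3)


class Lfsr:
    """Fibonacci linear feedback shift register over 4 bits.

    Parameters
    ----------
    seed : int
        Initial register value, must lie in ``1..15`` (the all-zero state is
        a fixed point of XOR feedback and therefore forbidden).
    taps : tuple of int
        1-based tap positions counted from the least significant bit.  The
        default ``(4, 3)`` realizes the primitive polynomial
        ``x^4 + x^3 + 1`` with period 15.
    """

    n_bits = 4

    def __init__(self, seed: int = 1, taps: tuple[int, int] = MAXIMAL_TAPS):
        seed = int(seed)
        if not 1 <= seed < (1 << self.n_bits):
            raise ValueError(
                f"LFSR register must be in 1..{(1 << self.n_bits) - 1}, got {seed}"
            )
        for t in taps:
            if not 1 <= t <= self.n_bits:
                raise ValueError(f"tap position {t} outside 1..{self.n_bits}")
        self.register = seed
        self.taps = tuple(int(t) for t in taps)

    def step(self) -> int:
        """Advance one clock tick and return the new register value."""
        if self.register == 0:
            raise ValueError("LFSR register reached the forbidden all-zero state")
        feedback = 0
        for t in self.taps:
            feedback ^= (self.register >> (t - 1)) & 1
        self.register = ((self.register << 1) | feedback) & ((1 << self.n_bits) - 1)
        return self.register

    def noise_frame(self) -> np.ndarray:
        """Emit one 16-cell noise frame with exactly one ON cell.

        The ON cell sits at linear index ``(register - 1) mod 16`` (row-major
        over the 4x4 field) so the unreachable zero register leaves no hole in
        the coverage; the register is then advanced for the next frame.
        """
        frame = np.zeros(FIELD_SIZE, dtype=np.uint8)
        frame[(self.register - 1) % FIELD_SIZE] = 1
        self.step()
        return frame

    def orbit(self) -> list[int]:
        """Register values visited from the current state until it recurs."""
        start = self.register
        seen = [start]
        self.step()
        while self.register != start:
            seen.append(self.register)
            self.step()
        return seen

    def __repr__(self) -> str:  # pragma: no cover
        return f"Lfsr(register={self.register}, taps={self.taps})"
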
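"""Lumped electrode-tissue measurement model.

The tissue potential is measured through a voltage divider formed by the
electrode-tissue interface impedance Z_e and the amplifier input impedance
Z_in:

    H(f) = Z_in(f) / (Z_in(f) + Z_e(f))

with

    Z_e(f) = R_s(A) + ( r_ct/A || 1 / (j 2 pi f c_dl A) )

where A is the contact surface area, c_dl the double-layer capacitance per
unit area, r_ct the area-normalized charge-transfer resistance, and R_s the
disc spreading resistance R_s = rho_t / (4 sqrt(A/pi)).  Larger contacts
present a smaller interface impedance, so |H| grows (weakly) with area and
is always in (0, 1].  Johnson noise of the interface, one-sided PSD
4 k_B T Re(Z_e), is added at the amplifier input after the divider.

Defaults are literature-scale values for platinum contacts; every constant
is a field of :class:`ElectrodeModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ElectrodeModel", "BOLTZMANN"]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class ElectrodeModel:
    """Platinum contact + amplifier front-end, parameterized by area.

    Units: area mm^2; c_dl F/mm^2; r_ct Ohm*mm^2; tissue_resistivity Ohm*m;
    z_in = (R_in Ohm, C_in F) in parallel; temperature K.
    """

    area: float = 1.08
    c_dl: float = 0.2e-6
    r_ct: float = 1.0e6
    tissue_resistivity: float = 3.0
    z_in: tuple[float, float] = (100e6, 10e-12)
    temperature: float = 310.0
    material: str = "platinum"

    def __post_init__(self) -> None:
        vals = (self.area, self.c_dl, self.r_ct, self.tissue_resistivity,
                self.z_in[0], self.z_in[1], self.temperature)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all electrode circuit parameters must be finite and > 0")

    def with_area(self, area: float) -> "ElectrodeModel":
        return replace(self, area=area)

    # -- impedances -------------------------------------------------------

    def spreading_resistance(self) -> float:
        """Disc spreading resistance R_s = rho_t / (4 a), a = sqrt(A/pi) in m."""
        radius_m = np.sqrt(self.area / np.pi) * 1e-3
        return self.tissue_resistivity / (4.0 * radius_m)

    def z_electrode(self, f: np.ndarray) -> np.ndarray:
        """Complex interface impedance Z_e(f) in Ohm (f in Hz, >= 0)."""
        f = np.asarray(f, dtype=float)
        r_ct_eff = self.r_ct / self.area
        c_eff = self.c_dl * self.area
        # r_ct in parallel with the double-layer capacitance
        y = 1.0 / r_ct_eff + 1j * 2 * np.pi * f * c_eff
        return self.spreading_resistance() + 1.0 / y

    def z_input(self, f: np.ndarray) -> np.ndarray:
        """Amplifier input impedance R_in || C_in, in Ohm."""
        f = np.asarray(f, dtype=float)
        r_in, c_in = self.z_in
        y = 1.0 / r_in + 1j * 2 * np.pi * f * c_in
        return 1.0 / y

    def transfer(self, f: np.ndarray) -> np.ndarray:
        """Divider transfer H(f) = Z_in / (Z_in + Z_e); |H| in (0, 1]."""
        z_in = self.z_input(f)
        z_e = self.z_electrode(f)
        return z_in / (z_in + z_e)

    def thermal_noise_psd(self, f: np.ndarray) -> np.ndarray:
        """One-sided Johnson-noise PSD 4 k_B T Re(Z_e), in uV^2/Hz."""
        re = np.real(self.z_electrode(f))
        return 4.0 * BOLTZMANN * self.temperature * re * 1e12

    # -- application ------------------------------------------------------

    def apply(self, potential: np.ndarray, fs: float,
              rng: np.random.Generator | None = None,
              add_noise: bool = True) -> np.ndarray:
        """Measure a tissue potential (uV) through the divider.

        Frequency-domain multiplication by H(f); optionally adds interface
        Johnson noise at the amplifier input (i.e. after the divider).
        """
        x = np.asarray(potential, dtype=float)
        n = x.shape[-1]
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        out = np.fft.irfft(np.fft.rfft(x) * self.transfer(freqs), n=n)
        if add_noise:
            if rng is None:
                raise ValueError("add_noise=True requires an rng")
            out = out + synthesize_from_psd(self.thermal_noise_psd(freqs), n, fs, rng)
        return out


def synthesize_from_psd(psd_onesided: np.ndarray, n: int, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a prescribed one-sided PSD (uV^2/Hz).

    rFFT synthesis: each positive-frequency bin gets an independent complex
    Gaussian with E|X_k|^2 = n * fs * S_k / 2, so the periodogram
    2 |X_k|^2 / (n fs) has expectation S_k.
    """
    n_bins = n // 2 + 1
    scale = np.sqrt(np.maximum(psd_onesided, 0.0) * n * fs / 2.0)
    x_f = scale * (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) / np.sqrt(2)
    x_f[0] = 0.0
    if n % 2 == 0:
        x_f[-1] = x_f[-1].real * np.sqrt(2)
    return np.fft.irfft(x_f, n=n)
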
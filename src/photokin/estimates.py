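"""Order-of-magnitude comparison of active patterning with passive optical trapping.

Closed forms contrasting the photokinetic (active) density-shaping scheme
with what optical forces on Brownian colloids would require:

* Passive colloids obey the Boltzmann law, ``log(rho_max/rho_min) = -dU/kBT``;
  in the Rayleigh regime the optical energy of a bead of radius ``a`` in a
  power density ``I`` is ``dU ~ a^3 I / c``, so unit log-contrast needs
  ``I ~ kBT c / a^3`` — about 1 W/mm^2 for a 1 um bead, three orders of
  magnitude above the projector powers the active scheme uses.
* Pattern formation times follow from drift and diffusion over the largest
  pattern scale ``l``: ``tau_drift = l / v`` and ``tau_diff = l^2 / (2 D)``,
  with the *prefactor-free* active diffusivity ``D = v^2 tau`` (run duration
  for run-and-tumble, reorientation time for smooth swimmers).  These
  order-of-magnitude conventions are kept literally here; the simulator uses
  the dimensionally exact 2-D value ``D_eff = v^2 tau_rot / 2``.

All functions are pure; units are in the argument names (um, s, pN, W/mm^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_J_PER_K",
    "SPEED_OF_LIGHT_M_S",
    "thermal_energy_J",
    "thermal_energy_pN_um",
    "boltzmann_log_contrast",
    "rayleigh_energy",
    "required_power_density",
    "active_diffusivity",
    "drift_time",
    "diffusion_time",
    "einstein_diffusivity",
    "brownian_drift_time",
    "order_of_magnitude",
    "summary_table",
]

BOLTZMANN_J_PER_K = 1.380649e-23
SPEED_OF_LIGHT_M_S = 299_792_458.0
DEFAULT_TEMPERATURE_K = 298.0


def thermal_energy_J(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """kBT in joules (default 298 K, water at room temperature)."""
    if temperature_K < 0:
        raise ValueError("temperature must be non-negative")
    return BOLTZMANN_J_PER_K * temperature_K


def thermal_energy_pN_um(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """kBT in pN um (4.11e-3 at 298 K)."""
    return thermal_energy_J(temperature_K) * 1e18  # J = N m -> pN um is 1e12 * 1e6


def boltzmann_log_contrast(
    delta_U_J: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """log(rho_max/rho_min) = -dU/kBT for a passive suspension in a potential."""
    return -delta_U_J / thermal_energy_J(temperature_K)


def rayleigh_energy(radius_um: float, power_density_W_mm2: float) -> float:
    """Optical energy scale ``dU = a^3 I / c`` (joules) of a Rayleigh bead.

    ``a`` in um, ``I`` in W/mm^2; order-of-magnitude convention, no
    polarizability prefactors.
    """
    if radius_um <= 0 or power_density_W_mm2 < 0:
        raise ValueError("radius must be positive, power density non-negative")
    a_m = radius_um * 1e-6
    I_W_m2 = power_density_W_mm2 * 1e6
    return a_m**3 * I_W_m2 / SPEED_OF_LIGHT_M_S


def required_power_density(
    radius_um: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Power density (W/mm^2) giving unit log density contrast: ``I = kBT c / a^3``."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    a_m = radius_um * 1e-6
    I_W_m2 = thermal_energy_J(temperature_K) * SPEED_OF_LIGHT_M_S / a_m**3
    return I_W_m2 / 1e6


def active_diffusivity(v_um_s: float, tau_s: float) -> float:
    """Prefactor-free active diffusivity ``D = v^2 tau`` (um^2/s).

    ``tau`` is the run duration (run-and-tumble) or the reorientation time
    (smooth swimmer).  Order-of-magnitude convention — the exact 2-D result
    would carry a factor 1/2.
    """
    if v_um_s < 0 or tau_s < 0:
        raise ValueError("v and tau must be non-negative")
    return v_um_s**2 * tau_s


def drift_time(length_um: float, v_um_s: float) -> float:
    """Drift (ballistic transport) timescale ``tau = l / v`` in seconds."""
    if v_um_s <= 0:
        raise ValueError("speed must be positive")
    if length_um <= 0:
        raise ValueError("length must be positive")
    return length_um / v_um_s


def diffusion_time(length_um: float, D_um2_s: float) -> float:
    """Diffusive transport timescale ``tau = l^2 / (2 D)`` in seconds."""
    if D_um2_s <= 0:
        raise ValueError("diffusivity must be positive")
    if length_um <= 0:
        raise ValueError("length must be positive")
    return length_um**2 / (2.0 * D_um2_s)


def einstein_diffusivity(
    mobility_um_s_pN: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Einstein relation ``D = mu kBT`` (um^2/s) for mobility in um/(s pN)."""
    if mobility_um_s_pN <= 0:
        raise ValueError("mobility must be positive")
    return mobility_um_s_pN * thermal_energy_pN_um(temperature_K)


def brownian_drift_time(
    length_um: float,
    mobility_um_s_pN: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Drift timescale of an optically driven colloid, ``l^2 / (mu kBT)`` seconds.

    Note: dimensional analysis requires l^2 here (mu kBT is a diffusivity);
    a frequently quoted variant divides by l instead, which yields a
    velocity, so this package reports the l^2 form only.
    """
    return length_um**2 / einstein_diffusivity(mobility_um_s_pN, temperature_K)


def order_of_magnitude(x: float) -> float:
    """Nearest power of ten: ``10**round(log10(x))``; deterministic reporting mode."""
    if x <= 0:
        raise ValueError("x must be positive")
    return 10.0 ** round(np.log10(x))


def summary_table(
    length_um: float = 1000.0,
    v_um_s: float = 5.0,
    tau_run_s: float = 1.0,
    tau_rot_s: float = 20.0,
    radius_um: float = 1.0,
    mobility_um_s_pN: float = 50.0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Labeled table of all the comparison numbers for the given scales.

    Defaults: 1 mm pattern scale, 5 um/s swimmers, 1 s runs, 20 s smooth-
    swimmer reorientation, 1 um bead of mobility 50 um/(s pN).
    """
    D_rt = active_diffusivity(v_um_s, tau_run_s)
    D_sm = active_diffusivity(v_um_s, tau_rot_s)
    D_br = einstein_diffusivity(mobility_um_s_pN, temperature_K)
    rows = [
        ("active drift time", "l/v", drift_time(length_um, v_um_s), "s"),
        ("active diffusion time (run-and-tumble)", "l^2/(2 v^2 tau_run)",
         diffusion_time(length_um, D_rt), "s"),
        ("active diffusion time (smooth swimmer)", "l^2/(2 v^2 tau_rot)",
         diffusion_time(length_um, D_sm), "s"),
        ("Brownian colloid diffusivity", "mu kBT", D_br, "um^2/s"),
        ("Brownian diffusion time", "l^2/(2 mu kBT)",
         diffusion_time(length_um, D_br), "s"),
        ("Brownian drift time", "l^2/(mu kBT)",
         brownian_drift_time(length_um, mobility_um_s_pN, temperature_K), "s"),
        ("required optical power density", "kBT c/a^3",
         required_power_density(radius_um, temperature_K), "W/mm^2"),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "formula", "value", "units"])
    df["order_of_magnitude"] = [order_of_magnitude(v) for v in df["value"]]
    return df
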
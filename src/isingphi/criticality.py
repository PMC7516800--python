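"""Temperature sweeps, susceptibility peaks, and ensemble summaries.

For one network the pipeline per temperature is: run the Metropolis
simulation, build the synchronous state-by-node TPM, evaluate Phi once per
distinct visited state (cached), and summarize every observable.  Across an
ensemble of random networks the per-temperature curves are averaged and the
critical temperature is estimated as the peak of the ensemble-mean magnetic
susceptibility; the headline comparison is whether the generalized
susceptibility of Phi peaks at the same temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phi as phi_mod
from .networks import ConnectivityMatrix
from .observables import (
    ensemble_variance,
    magnetic_susceptibility,
    specific_heat,
    time_average,
)
from .simulation import SimulationConfig, simulate
from .tpm import build_state_by_node_tpm

__all__ = [
    "SweepResult",
    "EnsembleSummary",
    "sweep_network",
    "sweep_ensemble",
    "find_peak",
    "summarize_ensemble",
    "plot_ensemble",
]

#: Width of the centered moving average applied before peak detection.
SMOOTHING_WINDOW = 5

_OBSERVABLES = ("M_mean", "E_mean", "chi", "Cv", "phi_mean", "chi_phi")


@dataclass(frozen=True)
class SweepResult:
    """All observables of one network as functions of temperature."""

    network_label: str
    temperatures: np.ndarray
    curves: dict[str, np.ndarray]  # keys: _OBSERVABLES
    n_nodes: int
    update_mode: str
    seed: int
    phi_computed: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"temperature": self.temperatures, **self.curves})
        df.insert(0, "network", self.network_label)
        return df

    def peak_temperature(self, observable: str, smooth: bool = True) -> float:
        return find_peak(
            self.temperatures, self.curves[observable], smooth=smooth
        )[0]

    @property
    def tc_chi(self) -> float:
        return self.peak_temperature("chi")

    @property
    def tc_cv(self) -> float:
        return self.peak_temperature("Cv")

    @property
    def tc_chi_phi(self) -> float:
        return self.peak_temperature("chi_phi")


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise means, standard deviations and across-network variances."""

    temperatures: np.ndarray
    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    sigma_j2: dict[str, np.ndarray]
    n_networks: int
    consensus_tc_chi: float
    consensus_tc_cv: float
    consensus_tc_chi_phi: float | None
    per_network_tc_chi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {"temperature": self.temperatures}
        for name in _OBSERVABLES:
            cols[f"{name}__mean"] = self.mean[name]
            cols[f"{name}__std"] = self.std[name]
            cols[f"{name}__sigmaJ2"] = self.sigma_j2[name]
        return pd.DataFrame(cols)


def _temperature_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
        % (2**31)
    )


def sweep_network(
    net: ConnectivityMatrix,
    temperatures: np.ndarray,
    n_thermalization: int = 500,
    n_iterations: int = 2000,
    update_mode: str = "sequential",
    compute_phi: bool = False,
    phi_weighting: str = "visit",
    seed: int = 0,
) -> SweepResult:
    """Sweep one network over a temperature grid.

    Each temperature runs an independent simulation (seed derived
    deterministically from ``(seed, temperature index)``, so per-temperature
    work units can run in any order or concurrently with identical results).
    When ``compute_phi`` is set, the state-by-node TPM is built at each
    temperature and Phi is evaluated once per distinct visited state.

    Sweeps default to *sequential* updates: that chain satisfies detailed
    balance, so its time averages are canonical-ensemble averages and the
    susceptibility peak is the physical one.  Phi is always computed from
    the synchronous state-by-node TPM regardless of how the trace was
    sampled (the kernel is what IIT analyses; the trace only supplies the
    visited states and their weights).
    """
    temperatures = np.asarray(temperatures, dtype=float)
    curves = {name: np.full(len(temperatures), np.nan) for name in _OBSERVABLES}
    for k, T in enumerate(temperatures):
        config = SimulationConfig(
            temperature=float(T),
            n_thermalization=n_thermalization,
            n_iterations=n_iterations,
            update_mode=update_mode,
            seed=_temperature_seed(seed, k),
        )
        trace = simulate(net, config)
        curves["M_mean"][k] = time_average(trace.magnetization)
        curves["E_mean"][k] = time_average(trace.energy)
        curves["chi"][k] = magnetic_susceptibility(trace.magnetization, T)
        curves["Cv"][k] = specific_heat(trace.energy, T)
        if compute_phi:
            sbn = build_state_by_node_tpm(net, float(T))
            res = phi_mod.phi_over_trace(trace, sbn, weighting=phi_weighting)
            curves["phi_mean"][k] = res.phi_mean
            curves["chi_phi"][k] = res.chi_phi
    return SweepResult(
        network_label=net.label,
        temperatures=temperatures,
        curves=curves,
        n_nodes=net.n_nodes,
        update_mode=update_mode,
        seed=seed,
        phi_computed=compute_phi,
    )


def sweep_ensemble(
    nets,
    temperatures: np.ndarray,
    master_seed: int = 0,
    **kwargs,
) -> list[SweepResult]:
    """Sweep every network of an ensemble with independent derived seeds."""
    results = []
    for k, net in enumerate(nets):
        seed = int(
            np.random.SeedSequence([master_seed, 7919, k]).generate_state(1)[0]
            % (2**31)
        )
        results.append(
            sweep_network(net, temperatures, seed=seed, **kwargs)
        )
        # per-network TPM engines are not needed across networks
        phi_mod.clear_caches()
    return results


def moving_average(values: np.ndarray, window: int = SMOOTHING_WINDOW):
    """Centered moving average with shrinking windows at the edges."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def find_peak(
    temperatures: np.ndarray,
    values: np.ndarray,
    smooth: bool = True,
    window: int = SMOOTHING_WINDOW,
) -> tuple[float, float]:
    """Temperature and height of the maximum of a curve.

    Raw Monte-Carlo curves are noisy, so a centered moving average (5 grid
    points) is applied by default before locating the maximum.  Ties are
    broken toward the lowest temperature; a flat curve triggers a
    degenerate-peak warning.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    values = np.asarray(values, dtype=float)
    if temperatures.shape != values.shape:
        raise ValueError("temperature grid and curve must align")
    y = moving_average(values, window) if smooth else values
    if np.allclose(y, y[0]):
        warnings.warn("curve is constant; peak is degenerate", stacklevel=2)
        return float(temperatures[0]), float(values[0])
    k = int(np.argmax(y))  # argmax takes the first (lowest-T) maximum
    return float(temperatures[k]), float(values[k])


def summarize_ensemble(results: list[SweepResult]) -> EnsembleSummary:
    """Pointwise ensemble statistics and the consensus critical temperature.

    The consensus Tc is the peak of the ensemble-*mean* susceptibility curve
    (the quantity plotted in the study's summary figure); per-network peaks
    are also reported.
    """
    if len(results) < 2:
        raise ValueError("ensemble summary needs at least 2 networks")
    temps = results[0].temperatures
    for r in results[1:]:
        if not np.array_equal(r.temperatures, temps):
            raise ValueError("all sweeps must share the temperature grid")
    mean, std, sj2 = {}, {}, {}
    for name in _OBSERVABLES:
        stack = np.vstack([r.curves[name] for r in results])
        mean[name] = stack.mean(axis=0)
        std[name] = stack.std(axis=0)
        sj2[name] = np.array(
            [ensemble_variance(stack[:, k]) for k in range(stack.shape[1])]
        )
    phi_ok = all(r.phi_computed for r in results)
    return EnsembleSummary(
        temperatures=temps,
        mean=mean,
        std=std,
        sigma_j2=sj2,
        n_networks=len(results),
        consensus_tc_chi=find_peak(temps, mean["chi"])[0],
        consensus_tc_cv=find_peak(temps, mean["Cv"])[0],
        consensus_tc_chi_phi=(
            find_peak(temps, mean["chi_phi"])[0] if phi_ok else None
        ),
        per_network_tc_chi=np.array([r.tc_chi for r in results]),
    )


def plot_ensemble(summary: EnsembleSummary, path=None, variances=False):
    """2x3 panel figure of the ensemble curves.

    Default layout mirrors the study's summary figure: order parameters
    (M, E, Phi) on the left of each pair, susceptibilities (chi, Cv,
    chi_Phi) on the right; ``variances=True`` plots the across-network
    variances instead.  Error bars are the standard deviation across
    networks.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("M_mean", "M"),
        ("chi", r"$\chi$"),
        ("E_mean", "E"),
        ("Cv", r"$C_v$"),
        ("phi_mean", r"$\Phi$"),
        ("chi_phi", r"$\chi_\Phi$"),
    ]
    fig, axes = plt.subplots(3, 2, figsize=(9, 10), sharex=True)
    for ax, (name, label) in zip(axes.ravel(), panels):
        if variances:
            ax.plot(summary.temperatures, summary.sigma_j2[name], "-")
            ax.set_ylabel(rf"$\sigma_J^2$({label})")
        else:
            ax.errorbar(
                summary.temperatures,
                summary.mean[name],
                yerr=summary.std[name],
                fmt="-",
                lw=1,
                elinewidth=0.5,
            )
            ax.set_ylabel(label)
        ax.set_xscale("log")
    for ax in axes[-1]:
        ax.set_xlabel("temperature")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
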
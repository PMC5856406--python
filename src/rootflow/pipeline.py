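"""End-to-end analysis pipeline.

Orchestrates geometry construction, synthetic ensemble generation (or
ingestion of externally measured fields), ensemble statistics, synthetic
orifice planimetry and the metrics report — deterministically for a given
master seed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from skimage import transform

from rootflow.config import RunConfig
from rootflow.geometry import (
    Grid,
    RootParameters,
    make_domain_masks,
    normalized_diameters,
)
from rootflow.planimetry import render_orifice_image, poa_series
from rootflow.stats import (
    METRIC_WINDOWS,
    MetricsReport,
    dimensionless_numbers,
    kinetic_energies,
    net_flow_rate,
    phase_statistics,
    rf_flow_rate,
    window_metrics,
)
from rootflow.synth import (
    DEFAULT_POA_MM2,
    JetFlowParams,
    PhaseEnsemble,
    PulseWaveform,
    generate_ensemble,
)

__all__ = ["analyze_ensemble", "synthetic_poa_frames", "measure_poa", "run_pipeline"]

log = logging.getLogger("rootflow")


def analyze_ensemble(
    ensemble: PhaseEnsemble,
    valve_tip_y: float = 14.5,
    rho: float = 1200.0,
    nu_mm2s: float = 4.7,
    A_poa_mm2: float | None = None,
    d_p_um: float = 42.0,
    rho_p: float = 1180.0,
) -> MetricsReport:
    """Full statistical post-processing of one phase-locked ensemble.

    Computes per-phase means and RMS fields, net/retrograde flow rates at
    the flow coordinate Y = 0 (one annulus diameter above the valve
    tips), mean/fluctuating kinetic energies in the Omega1 / Omega2 /
    OmegaS domains, the windowed scalar metrics, and the dimensionless
    numbers.
    """
    geom = ensemble.geom
    grid = ensemble.grid
    with warnings.catch_warnings():
        if not geom.has_sinus:
            warnings.simplefilter("ignore")
        masks = make_domain_masks(geom, grid, valve_tip_y)
    flow_origin = valve_tip_y + geom.d_a
    times = ensemble.phase_times

    series = {
        name: np.zeros(len(times))
        for name in (
            "Q_net", "Q_RF",
            "E_MK_O1", "E_FK_O1", "E_MK_O2", "E_FK_O2", "E_MK_OS", "E_FK_OS",
        )
    }
    for j in range(ensemble.n_phases):
        mean, rms = phase_statistics(ensemble, j)
        mean.flow_origin_y = flow_origin
        series["Q_net"][j] = net_flow_rate(mean, 0.0)
        series["Q_RF"][j] = rf_flow_rate(mean, 0.0)
        for dom, tag in (("Omega1", "O1"), ("Omega2", "O2"), ("OmegaS", "OS")):
            e_mk, e_fk = kinetic_energies(mean, rms, masks[dom], rho)
            series[f"E_MK_{tag}"][j] = e_mk
            series[f"E_FK_{tag}"][j] = e_fk
        log.debug("phase %d (t=%.2f s) processed", j, times[j])

    e_tj = window_metrics(times, series["E_FK_O2"], *METRIC_WINDOWS["E_TJ"])
    q_rf = window_metrics(times, series["Q_RF"], *METRIC_WINDOWS["Q_RF"])
    e_mks = window_metrics(times, series["E_MK_OS"], *METRIC_WINDOWS["E_MKS"])

    if A_poa_mm2 is None:
        A_poa_mm2 = DEFAULT_POA_MM2.get(geom.label, np.pi * ensemble.jet.r_jet**2)
    dims = dimensionless_numbers(
        Q_max_lmin=ensemble.waveform.Q_max_lmin,
        A_poa_mm2=A_poa_mm2,
        nu_mm2s=nu_mm2s,
        r_a_mm=geom.r_a,
        T_s=ensemble.waveform.T,
        rho=rho,
        rho_p=rho_p,
        d_p_um=d_p_um,
    )
    delta_sov, delta_aao = normalized_diameters(geom, dims.d_jet_mm)

    return MetricsReport(
        label=geom.label,
        times=times,
        series=series,
        E_TJ_mJ=e_tj * 1.0e3,
        Q_RF_m3s=q_rf,
        E_MKS_mJ=e_mks * 1.0e3,
        delta_SOV=delta_sov,
        delta_AAo=delta_aao,
        d_jet_mm=dims.d_jet_mm,
        Re=dims.Re,
        alpha=dims.alpha,
        St=dims.St,
        degenerate_sinus=not geom.has_sinus,
        notes={
            "flow_origin": "Y=0 one annulus diameter above the valve tips",
            "rms_divisor": "population (N)",
            "windows_s": METRIC_WINDOWS,
            "A_poa_mm2": A_poa_mm2,
            "n_fields": len(ensemble),
        },
    )


def synthetic_poa_frames(
    A_max_mm2: float,
    waveform: PulseWaveform | None = None,
    fps: float = 200.0,
    n_pulses: int = 1,
    t_end: float = 0.36,
    opening_duration: float = 0.03,
    closing_start: float = 0.24,
    closing_duration: float = 0.06,
    noise_sd: float = 0.03,
    seed: int = 0,
    distortion: transform.AffineTransform | None = None,
):
    """Synthetic axial-camera sequence for one or more pulses.

    The valve opens over ``opening_duration`` starting at the waveform's
    opening delay, stays at ``A_max_mm2`` through mid-systole, and closes
    over ``closing_duration`` from ``closing_start``.  All frames share
    one perspective distortion (as one fixed camera would) and
    independent additive noise.
    """
    waveform = waveform or PulseWaveform()
    if distortion is None:
        distortion = transform.AffineTransform(
            shear=0.08, rotation=0.03, scale=(1.04, 0.97),
            translation=(3.0, -2.0),
        )
    frames = []
    times = np.arange(0.0, n_pulses * waveform.T, 1.0 / fps)
    times = times[np.mod(times, waveform.T) <= t_end + 1e-9]
    for i, t in enumerate(times):
        tau = float(np.mod(t, waveform.T))
        if tau < waveform.t_open:
            a = 0.0
        elif tau < waveform.t_open + opening_duration:
            a = A_max_mm2 * (tau - waveform.t_open) / opening_duration
        elif tau < closing_start:
            a = A_max_mm2
        elif tau < closing_start + closing_duration:
            a = A_max_mm2 * (1.0 - (tau - closing_start) / closing_duration)
        else:
            a = 0.0
        frames.append(
            render_orifice_image(
                a, distortion=distortion, noise_sd=noise_sd,
                seed=seed + i, t=float(t),
            )
        )
    return frames


def measure_poa(
    A_max_mm2: float,
    waveform: PulseWaveform | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
    n_pulses: int = 1,
):
    """Render and analyse a synthetic orifice sequence; returns the
    :class:`~rootflow.planimetry.POASeries`."""
    waveform = waveform or PulseWaveform()
    frames = synthetic_poa_frames(
        A_max_mm2, waveform=waveform, noise_sd=noise_sd, seed=seed,
        n_pulses=n_pulses,
    )
    ref = frames[0].truth["landmarks"]
    return poa_series(frames, reference_landmarks=ref,
                      period=waveform.T if n_pulses > 1 else None)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run geometry -> synthesis -> statistics -> planimetry -> report for
    every configured phantom.  Returns ``{label: MetricsReport}`` and
    writes one JSON report and one per-phase CSV per phantom."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    waveform = PulseWaveform(
        T=config.waveform.get("T_s", 60.0 / 72.0),
        Q_max_lmin=config.waveform.get("Q_max_lmin", 20.0),
        f_sys=config.waveform.get("f_sys", 1.0 / 3.0),
        shape=config.waveform.get("shape", "trapezoid"),
        f_ramp=config.waveform.get("f_ramp", 0.27),
        t_open=config.waveform.get("t_open_s", 0.06),
    )
    reports: dict[str, MetricsReport] = {}
    n_fields_total = 0
    for geom in config.root_parameters():
        label = geom.label
        a_poa_target = (config.A_poa_mm2 or {}).get(
            label, DEFAULT_POA_MM2.get(label, 180.0)
        )
        if config.planimetry_enabled:
            poa = measure_poa(
                a_poa_target, waveform=waveform,
                noise_sd=config.planimetry_noise_sd, seed=config.seed,
            )
            a_poa = poa.A_poa_mm2
            poa_frame = np.column_stack([poa.times, poa.areas_mm2])
            np.savetxt(
                out / f"poa_{label}.csv", poa_frame, delimiter=",",
                header="time_s,area_mm2", comments="",
            )
        else:
            a_poa = a_poa_target
        jet = JetFlowParams.for_phantom(geom, a_poa, **config.jet)
        grid = Grid.for_root(geom, config.grid_spacing_mm)
        ensemble = generate_ensemble(
            geom, jet, waveform, grid,
            n_replicates=config.n_replicates,
            master_seed=config.seed,
            n_phases=config.n_phases,
            dt=config.dt_s,
        )
        n_fields_total += len(ensemble)
        log.info("phantom %s: %d fields on a %s grid", label, len(ensemble),
                 "x".join(map(str, grid.counts)))
        report = analyze_ensemble(
            ensemble,
            valve_tip_y=config.valve_height_mm,
            rho=config.rho_kgm3,
            nu_mm2s=config.nu_mm2s,
            A_poa_mm2=a_poa,
            d_p_um=config.d_p_um,
            rho_p=config.rho_p_kgm3,
        )
        report.notes["seed"] = config.seed
        report.to_json(out / f"report_{label}.json")
        report.series_frame().to_csv(out / f"series_{label}.csv", index=False)
        if config.save_fields:
            from rootflow.io import container_from_ensemble, write_fields

            write_fields(container_from_ensemble(ensemble),
                         out / f"fields_{label}.h5")
        reports[label] = report
    log.info("pipeline complete: %d phantoms, %d instantaneous fields",
             len(reports), n_fields_total)
    return reports
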
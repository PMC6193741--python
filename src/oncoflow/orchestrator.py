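"""Staggered multi-rate coupling loop and the experiment-matrix driver.

Every outer step (hours) executes, in order: biochemical solve (oxygen,
MDE, ECM), solid solve (growth mechanics), vascular network update
(sprouting, radius remodelling, re-embedding), fluid solve, drug solve
(sub-stepped), and a final vessel-state re-assessment with a fluid
re-solve.  The entire evolution is reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drug as drugmod
from . import fluid as fluidmod
from . import tissue as tissuemod
from . import vasculature as vascmod
from .config import SimulationConfig
from .coupling import embed_network
from .mesh import build_tissue_mesh
from .network import generate_network
from .params import Parameters, load_parameters
from .units import DAY, HOUR

log = logging.getLogger(__name__)


@dataclass
class SimulationResult:
    config: SimulationConfig
    metrics: pd.DataFrame
    peak_ifv: float              # m/s, time-max of averaged IFV
    peak_ch: float               # peak tumour-integrated c_h (m³·c units)
    mean_spacing0: float         # m, day-0 mean nearest-vessel distance
    final_volume: float          # m³ deformed tumour volume
    volume0: float
    params: Parameters = None
    sim: "Simulation" = None

    def volume_mm3(self, day: float) -> float:
        """Interpolated deformed tumour volume (mm³) at a given day."""
        m = self.metrics
        return float(np.interp(day, m["t_day"], m["volume_mm3"]))


class Simulation:
    """State of one coupled run; use :func:`run_simulation` for the loop."""

    def __init__(self, config: SimulationConfig,
                 params: Parameters | None = None, network=None):
        self.config = config
        p = params or load_parameters(config.params_path)
        # config-level sweep variables override the parameter file
        p.wall.pore_radius = config.pore_radius
        p.drug.k_on = config.k_on
        p.drug.molecule_size = config.molecule_size
        self.p = p
        self.rng = np.random.default_rng(
            [int(config.seed) % 2 ** 31, 2 ** 20 + 7])

        self.mesh = build_tissue_mesh(config.edge_length, config.resolution,
                                      config.tumour_radius)
        self.a0 = config.tumour_radius        # material tumour radius
        if network is None:
            network = generate_network(
                int(config.seed) % 2 ** 31, config.n_segments, self.mesh,
                wall_thickness=p.wall.thickness,
                pore_radius=p.wall.pore_radius,
                pore_fraction=p.wall.gamma_p)
        self.network = network
        self.n_segments0 = network.n_segments
        self.coupling = embed_network(self.mesh, self.network)
        self.D_c = drugmod.stokes_einstein_diffusivity(
            p.drug.molecule_size, p.drug.temperature, p.fluid.mu_interstitial)
        self.P_d, self.sigma_f = drugmod.hindrance_coefficients(
            p.drug.molecule_size, p.wall.pore_radius, p.wall.gamma_p,
            p.wall.thickness, self.D_c)
        self.K_vsc = fluidmod.wall_conductivity(
            p.wall.pore_radius, p.wall.gamma_p, p.wall.thickness,
            p.fluid.mu_plasma)

        n = self.mesh.n_nodes
        tum = self.mesh.tumour_mask
        self.ecm = np.where(tum, p.tissue.ecm_tumour_init,
                            p.tissue.ecm_host_init).astype(float)
        self.drug_state = drugmod.DrugState.zeros(self.network.n_nodes, n)
        self.t = 0.0                     # days
        self.xi_ref = None
        self.delta_ref = None
        self.last_wss = None
        self.rows = []
        self.peak_ifv = 0.0
        self.peak_ch = 0.0
        self._init_state()

    # ------------------------------------------------------------------
    def _solve_fluid(self):
        self.pressures = fluidmod.solve_coupled_pressures(
            self.network, self.mesh, self.coupling, self.p.lymph, self.p.fluid)
        gate = (self.p.metrics.supply_velocity_factor
                * self.p.metrics.perfusion_velocity)
        self.network.perfused = np.abs(self.pressures.v_vsc) > gate

    def _solve_oxygen(self):
        self.xi, ref = tissuemod.oxygen_surrogate(
            self.mesh, self.network, self.coupling, self.p.oxygen,
            reference=self.xi_ref)
        if self.xi_ref is None:
            self.xi_ref = ref

    def _solve_mechanics(self, dt_day: float | None = None):
        target, _ = tissuemod.growth_strain(self.xi, self.ecm, self.p.tissue)
        target = np.where(self.mesh.tumour_mask, target, 0.0)
        if dt_day is None:
            # initial condition: the tumour starts unstrained (V(0) is the
            # seeded 1 mm ball)
            self.theta_state = np.zeros(self.mesh.n_nodes)
        else:
            # the growth strain relaxes toward its Gompertz target at a
            # finite tissue-remodelling rate
            f = np.exp(-dt_day / self.p.tissue.tau_growth)
            self.theta_state = target + (self.theta_state - target) * f
            self.theta_state = np.clip(self.theta_state, 0.0, None)
        self.mech = tissuemod.solve_mechanics(self.mesh, self.theta_state,
                                              self.ecm, self.p.tissue, self.a0)
        r_T = min(self.mech.tumour_radius, 0.45 * self.mesh.edge_length)
        old_mask = self.mesh.tumour_mask
        self.mesh.set_tumour_radius(r_T)
        new_mask = self.mesh.tumour_mask
        # material consistency of the advected indicator: nodes newly swept
        # by the tumour boundary are displaced tumour tissue and inherit the
        # tumour-mean state; nodes released on regression revert to host.
        entered = new_mask & ~old_mask
        left = old_mask & ~new_mask
        if entered.any() and old_mask.any():
            self.ecm[entered] = self.ecm[old_mask].mean()
            self.theta_state[entered] = self.theta_state[old_mask].mean()
        if left.any():
            self.ecm[left] = self.p.tissue.ecm_host_init
            self.theta_state[left] = 0.0
            # cell-associated drug in released nodes stays in place as
            # inert debris (all rates are zero outside the tumour); it is
            # re-engaged if the boundary sweeps back over it
        self.thp_node = self.mech.thp_at_spatial(self.mesh.radii)
        disp = self.mech.displacement_at(self.network.material_nodes,
                                         self.mesh.centre)
        self.network.displace(disp)
        np.clip(self.network.nodes, 0.0, self.mesh.edge_length,
                out=self.network.nodes)

    def _init_state(self):
        self._solve_fluid()
        self._solve_oxygen()
        self.mde = tissuemod.mde_surrogate(self.mesh, self.mesh.tumour_mask,
                                           self.p.mde)
        self._solve_mechanics()
        self.coupling = embed_network(self.mesh, self.network)
        self._solve_fluid()
        self.volume0 = self.mech.tumour_volume
        self.last_wss = vascmod.wall_shear_stress(
            self.network, self.pressures.Q_vsc, self.p.fluid.mu_blood)
        am = vascmod.architecture_metrics(self.network, self.mesh,
                                          self.pressures.v_vsc,
                                          self.p.metrics)
        self.delta_ref = am.delta_max
        self.mean_spacing0 = am.mean_spacing
        self._record(am)

    # ------------------------------------------------------------------
    def _segment_samples(self):
        """(THP, p_int, p_vsc) sampled at segment midpoints."""
        mids = self.network.midpoints
        d = np.linalg.norm(mids - self.mesh.centre, axis=1)
        thp = self.mech.thp_at_spatial(d)
        p_int = np.asarray(self.coupling.midpoint_weights
                           @ self.pressures.p_int).ravel()
        p_vsc = 0.5 * (self.pressures.p_vsc[self.network.node_a]
                       + self.pressures.p_vsc[self.network.node_b])
        return thp, p_int, p_vsc

    def _drug_window(self, t0_day: float, dt_day: float):
        """Advance the drug fields over one outer window (days)."""
        cfg, p = self.config, self.p
        if cfg.inject_day is None:
            return
        t_end = t0_day + dt_day
        if t_end <= cfg.inject_day:
            return
        st = self.drug_state
        if len(st.c_v) != self.network.n_nodes:
            grown = np.zeros(self.network.n_nodes)
            grown[:len(st.c_v)] = st.c_v
            st.c_v = grown
        tum = self.mesh.tumour_mask
        live = self.network.functional() & self.network.perfused
        area = self.network.wall_area * live
        vols = self.mesh.node_volumes
        S_perf = np.asarray(self.coupling.distribution.T @ area).ravel() / vols
        # nodal projections of segment-borne quantities (area-weighted)
        Wd = self.coupling.distribution
        wsum = np.asarray(Wd.T @ area).ravel()
        c_seg_of = lambda cv: 0.5 * (cv[self.network.node_a]
                                     + cv[self.network.node_b])
        p_eff_seg = self.pressures.p_eff
        with np.errstate(invalid="ignore", divide="ignore"):
            p_eff_node = np.where(wsum > 0,
                                  np.asarray(Wd.T @ (area * p_eff_seg)).ravel()
                                  / np.maximum(wsum, 1e-300), 0.0)
        S_lmp = np.where(tum, p.lymph.S_lmp_tumour, p.lymph.S_lmp_host)

        chunk = cfg.drug_chunk_minutes * 60.0 / DAY   # days
        t = max(t0_day, cfg.inject_day)
        while t < t_end - 1e-12:
            dt = min(chunk, t_end - t)
            t_mid = t + dt / 2.0
            inlet = drugmod.bolus_concentration(t_mid * DAY,
                                                cfg.inject_day * DAY,
                                                p.drug.c_v_max, p.drug.tau_c)
            active_iv = inlet > 1e-10 or st.c_v.max(initial=0.0) > 1e-12
            if active_iv:
                st.c_v = drugmod.solve_intravascular_implicit(
                    self.network, self.pressures, inlet, st.c_v, dt * DAY, st)
            tissue_total = st.c_f.sum() + st.c_b.sum() + st.c_i.sum()
            if active_iv or tissue_total > 1e-14:
                with np.errstate(invalid="ignore", divide="ignore"):
                    c_v_node = np.where(
                        wsum > 0,
                        np.asarray(Wd.T @ (area * c_seg_of(st.c_v))).ravel()
                        / np.maximum(wsum, 1e-300), 0.0)
                # affine exchange split Φ = a − b·c_f (see drug module)
                dp = p_eff_node - self.pressures.p_int
                conv = self.K_vsc * S_perf * (1.0 - self.sigma_f)
                a_v = (self.P_d * S_perf * c_v_node
                       + conv * np.maximum(dp, 0.0) * c_v_node)
                b_v = self.P_d * S_perf + conv * np.maximum(-dp, 0.0)
                # lymphatics drain only (influx from the lymph carries lymph
                # concentration, i.e. none)
                lcoef = p.lymph.K_lmp * S_lmp * (p.lymph.p_lmp
                                                 - self.pressures.p_int)
                a_l = np.zeros(self.mesh.n_nodes)
                b_l = np.maximum(-lcoef, 0.0)
                drugmod.step_extravascular(
                    self.mesh, st, self.pressures.v_int, self.D_c,
                    (a_v, b_v, a_l, b_l), p.drug.k_on, p.drug.k_off,
                    p.drug.k_int, p.drug.delta_i, self.ecm, tum, dt * DAY)
            t += dt

    def _record(self, am: vascmod.ArchitectureMetrics):
        mask = self.mesh.shell_mask(self.p.metrics.shell_width)
        tum = self.mesh.tumour_mask
        vols = self.mesh.node_volumes
        st = self.drug_state
        ifv = self.pressures.averaged_ifv(mask)
        ch_int = float(((st.c_b + st.c_i) * vols)[tum].sum())
        self.peak_ifv = max(self.peak_ifv, ifv)
        self.peak_ch = max(self.peak_ch, ch_int)
        vol = self.mech.tumour_volume
        self.rows.append({
            "t_day": self.t,
            "V": vol / self.volume0 - 1.0 if hasattr(self, "volume0") else 0.0,
            "volume_mm3": vol * 1e9,
            "ifv": ifv,
            "ifp": self.pressures.averaged_ifp(mask),
            "thp": float(self.thp_node[mask].mean()),
            "delta_max_norm": am.delta_max_norm,
            "convexity": am.convexity,
            "fpv": am.perfused_fraction,
            "cf_int": float((st.c_f * vols)[tum].sum()),
            "cb_int": float((st.c_b * vols)[tum].sum()),
            "ci_int": float((st.c_i * vols)[tum].sum()),
            "ch_int": ch_int,
            "n_segments": self.network.n_segments,
            "n_collapsed": int((self.network.state == 2).sum()),
            "total_length": float(self.network.lengths.sum()),
            "xi_mean_tumour": float(self.xi[tum].mean()),
            "ecm_mean_tumour": float(self.ecm[tum].mean()),
        })

    # ------------------------------------------------------------------
    def step(self):
        cfg, p = self.config, self.p
        dt_day = cfg.dt_outer_hours * HOUR / DAY

        # 1. biochemical module
        self._solve_oxygen()
        self.mde = tissuemod.mde_surrogate(self.mesh, self.mesh.tumour_mask,
                                           self.p.mde)
        self.ecm = tissuemod.ecm_step(
            self.ecm, self.mde, self.xi, self.drug_state.c_i,
            self.mesh.tumour_mask, dt_day, p.tissue)

        # 2. solid module
        self._solve_mechanics(dt_day)

        # 3. vascular network module
        vascmod.sprout_surrogate(self.network, self.mesh, self.xi, self.rng,
                                 dt_day, p.vessels, self.n_segments0,
                                 region_mask=self.mesh.shell_mask(2.0e-3))
        if self.last_wss is not None:
            wss = np.zeros(self.network.n_segments)
            wss[:len(self.last_wss)] = self.last_wss
            vascmod.remodel_radii(self.network, wss, dt_day, p.vessels)
        self.coupling = embed_network(self.mesh, self.network)

        # 4. fluid module
        self._solve_fluid()

        # 5. drug module
        self._drug_window(self.t, dt_day)

        # 6. vessel-state re-assessment + fluid re-solve
        thp_s, p_int_s, p_vsc_s = self._segment_samples()
        old_state = self.network.state.copy()
        vascmod.update_vessel_states(self.network, thp_s, p_int_s, p_vsc_s,
                                     p.vessels)
        if not np.array_equal(old_state, self.network.state):
            self._solve_fluid()
        self.last_wss = vascmod.wall_shear_stress(
            self.network, self.pressures.Q_vsc, p.fluid.mu_blood)

        self.t += dt_day
        am = vascmod.architecture_metrics(self.network, self.mesh,
                                          self.pressures.v_vsc, p.metrics,
                                          delta_ref=self.delta_ref)
        self._record(am)

    def run(self) -> SimulationResult:
        n_steps = int(round(self.config.end_day
                            / (self.config.dt_outer_hours * HOUR / DAY)))
        for k in range(n_steps):
            self.step()
            if k % 20 == 0:
                log.info("%s: day %.2f V=%.3f", self.config.label(), self.t,
                         self.rows[-1]["V"])
        metrics = pd.DataFrame(self.rows)
        return SimulationResult(
            config=self.config, metrics=metrics, peak_ifv=self.peak_ifv,
            peak_ch=self.peak_ch, mean_spacing0=self.mean_spacing0,
            final_volume=self.mech.tumour_volume, volume0=self.volume0,
            params=self.p, sim=self)


def run_simulation(config: SimulationConfig,
                   params: Parameters | None = None) -> SimulationResult:
    """Run one simulation to its end day; deterministic in (config, seed)."""
    sim = Simulation(config, params=params)
    result = sim.run()
    if config.output_dir:
        from pathlib import Path

        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.metrics.to_csv(out / f"{config.label()}_metrics.csv",
                              index=False)
        config.to_yaml(out / f"{config.label()}_config.yaml")
    return result


def run_sweep(configs, params: Parameters | None = None) -> pd.DataFrame:
    """Run an experiment grid; returns a tidy table with one row per
    (config, time) sample.  Failures are recorded and the sweep continues."""
    frames = []
    for cfg in configs:
        try:
            res = run_simulation(cfg, params=params)
        except Exception as exc:            # noqa: BLE001 - sweep resilience
            log.error("run %s failed: %s", cfg.label(), exc)
            continue
        m = res.metrics.copy()
        m["run"] = cfg.label()
        m["pore_radius"] = cfg.pore_radius
        m["k_on"] = cfg.k_on
        m["inject_day"] = (np.nan if cfg.inject_day is None
                           else cfg.inject_day)
        m["peak_ifv"] = res.peak_ifv
        m["peak_ch"] = res.peak_ch
        frames.append(m)
    if not frames:
        raise RuntimeError("every run in the sweep failed")
    return pd.concat(frames, ignore_index=True)


def experiment_matrix(seed: int = 1, *, pore_radii=(1.0e-8, 1.5e-7),
                      affinities=(0.005, 5.0), inject_days=(10.0, 20.0, 30.0),
                      profile: str = "coarse", end_day: float = 40.0):
    """Configs for the poresize × affinity × injection-day matrix plus the
    matched controls."""
    make = (SimulationConfig.coarse if profile == "coarse"
            else SimulationConfig)
    cfgs = []
    for rp in pore_radii:
        cfgs.append(make(pore_radius=rp, k_on=affinities[0], inject_day=None,
                         end_day=end_day, seed=seed))
        for kon in affinities:
            for day in inject_days:
                cfgs.append(make(pore_radius=rp, k_on=kon, inject_day=day,
                                 end_day=end_day, seed=seed))
    return cfgs
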
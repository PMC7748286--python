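"""Transcription-factor network: rate laws, cell trajectories, profile
assembly, domain extraction and pattern scoring."""

import numpy as np
import pytest

from spinalgrn.tfnet import (
    GENES,
    HILL_CONSTANT_NAMES,
    OBSERVABLE_GENES,
    Cdx4Drive,
    SignalTrace,
    TFParams,
    TFProfile,
    assemble_spatial_profile,
    cell_signal_trace,
    check_pattern,
    extract_domains,
    simulate_cell,
    tf_rhs,
)


class TestRateLaws:
    def test_all_zero_is_a_fixed_point(self):
        d = tf_rhs(np.zeros(15), (0.0, 0.0, 0.0), TFParams())
        assert np.allclose(d, 0.0)  # Pax6's basal promoter is RA-gated shut

    def test_half_max_tbra_activation(self):
        p = TFParams()
        state = np.zeros(15)
        d = tf_rhs(state, (p.F_FT, 0.0, 0.0), p)
        assert d[0] == pytest.approx(0.5 * p.alpha_m)

    def test_pax6_at_cdx4_and_ra_hill_constants(self):
        # C = C_CP and R = R_RP: (1+1)/(1+1) * 1/2 = 1/2 of maximal rate
        p = TFParams()
        state = np.zeros(15)
        state[7] = p.C_CP        # CDX4 protein
        state[10] = 2.0          # existing Pax6 mRNA
        d = tf_rhs(state, (0.0, 0.0, p.R_RP), p)
        assert d[10] == pytest.approx(1.0 * 1.0 * 0.5 - p.beta_m * 2.0)

    def test_cdx4_drive_null_and_constitutive(self):
        p = TFParams()
        state = np.zeros(15)
        signals = (p.F_FC, 0.0, 0.0)
        assert tf_rhs(state, signals, p, cdx4_rate=0.0)[6] == 0.0
        boosted = tf_rhs(state, signals, p, cdx4_rate=Cdx4Drive(scale=1.0, const=2.0))
        normal = tf_rhs(state, signals, p)
        assert boosted[6] == pytest.approx(normal[6] + 2.0 * p.alpha_m)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            tf_rhs(np.full(15, np.nan), (0.0, 0.0, 0.0), TFParams())

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="F_FT"):
            TFParams(F_FT=-1.0)


def _constant_trace(F, W, R, duration=3000.0):
    t = np.arange(0.0, duration + 1.0)
    ones = np.ones_like(t)
    return SignalTrace(t=t, F=F * ones, W=W * ones, R=R * ones)


def _fixed_point_mrnas(params, F, W, R, iters=400):
    """Independent steady-state oracle: damped fixed-point iteration of the
    algebraic Hill equations (mRNA* = alpha_m/beta_m * regulation(protein*),
    protein* = alpha_p/beta_p * mRNA*)."""
    p = params
    m = np.zeros(8)  # Tm, Sm, NKm, Cm, Xm, Pm, Ym, Nm

    def proteins(m):
        ratio = p.alpha_p / p.beta_p
        prot = m[:7] * ratio
        prot[3] = m[3] * p.alpha_Cp / p.beta_Cp  # CDX4 stability
        return prot

    for _ in range(iters):
        T, S, NK, C, X, P, Y = proteins(m)
        u = lambda lvl, K: (lvl / K) ** 2
        reg = np.array([
            u(F, p.F_FT) / (1 + u(F, p.F_FT) + u(S, p.S_ST)),
            (u(F, p.F_FS) + u(R, p.R_RS)) / (1 + u(F, p.F_FS) + u(R, p.R_RS) + u(T, p.T_TS)),
            u(W, p.W_WNK) / (1 + u(W, p.W_WNK) + u(NK, p.NK_NKNK) + u(X, p.X_XNK)),
            (u(F, p.F_FC) + u(W, p.W_WC)) / (1 + u(F, p.F_FC) + u(W, p.W_WC) + u(Y, p.Y_YC)),
            u(C, p.C_CX) / (1 + u(C, p.C_CX) + u(F, p.F_FX)),
            (1 + u(C, p.C_CP)) / (1 + u(C, p.C_CP) + u(NK, p.NK_NKP))
            * u(R, p.R_RP) / (1 + u(R, p.R_RP)),
            u(P, p.P_PY) / (1 + u(P, p.P_PY) + u(F, p.F_FY)),
            u(P, p.P_PN2) / (1 + u(P, p.P_PN2) + u(X, p.X_XN2)),
        ])
        m = 0.5 * m + 0.5 * (p.alpha_m / p.beta_m) * reg
    return m


class TestCellSimulation:
    def test_zero_signals_stay_zero(self):
        traj = simulate_cell(_constant_trace(0.0, 0.0, 0.0, duration=500.0))
        assert np.allclose(traj.states, 0.0)

    def test_steady_state_matches_fixed_point_oracle(self):
        params = TFParams()
        F, W, R = 30.0, 10.0, 5.0
        traj = simulate_cell(_constant_trace(F, W, R, duration=6000.0), params)
        final = traj.final_state
        m_oracle = _fixed_point_mrnas(params, F, W, R)
        mrna_idx = [0, 2, 4, 6, 8, 10, 12, 14]
        assert np.allclose(final[mrna_idx], m_oracle, rtol=1e-3, atol=1e-9)
        # each converged protein equals alpha_p * mRNA* / beta_p
        for gene, mi in (("tbra", 0), ("sox2", 2), ("nkx12", 4), ("x", 8),
                         ("pax6", 10), ("y", 12)):
            pi = mi + 1
            assert final[pi] == pytest.approx(
                params.alpha_p * final[mi] / params.beta_p, rel=1e-3)
        assert final[7] == pytest.approx(
            params.alpha_Cp * final[6] / params.beta_Cp, rel=1e-3)

    def test_nonnegative_along_trajectory(self, balance):
        trace = cell_signal_trace(balance, birth_time=5200.0)
        traj = simulate_cell(trace)
        assert traj.states.min() >= 0.0


class TestSignalTrace:
    def test_trace_length_is_transit_time(self, balance):
        trace = cell_signal_trace(balance, birth_time=0.0)
        expected = 2500.0 / balance.velocity
        assert trace.t[-1] - trace.t[0] == pytest.approx(expected, abs=1.5)

    def test_birth_sample_equals_caudal_end(self, balance):
        trace = cell_signal_trace(balance, birth_time=4000.0)
        assert trace.F[0] == pytest.approx(balance.F[400, 0], rel=1e-9)
        assert trace.R[0] == pytest.approx(balance.R[400, 0], rel=1e-9)

    def test_stationary_field_traces_agree(self, balance):
        """Cells born during the settled balance regime see near-identical
        signal histories."""
        a = cell_signal_trace(balance, birth_time=4500.0)
        b = cell_signal_trace(balance, birth_time=5000.0)
        n = min(len(a.t), len(b.t))
        for sig in ("F", "W", "R"):
            va, vb = getattr(a, sig)[:n], getattr(b, sig)[:n]
            assert np.max(np.abs(va - vb)) < 0.03 * va.max()

    def test_birth_outside_window_rejected(self, balance):
        with pytest.raises(ValueError):
            cell_signal_trace(balance, birth_time=-5.0)


class TestProfileAssembly:
    def test_cohort_matches_per_cell_integration(self, balance):
        """The jointly integrated cohort agrees with independent single-cell
        solves at sampled positions."""
        positions = np.array([0.0, 500.0, 1250.0, 2000.0, 2500.0])
        profile = assemble_spatial_profile(balance, TFParams(), positions=positions)
        for k, xi in enumerate(positions):
            trace = cell_signal_trace(balance, birth_time=6000.0 - xi / 3.0)
            solo = simulate_cell(trace, TFParams()).final_state
            for gene, gi in GENES.items():
                got = profile.mrna[gene][k]
                ref = solo[gi]
                assert got == pytest.approx(ref, rel=1e-2, abs=1e-4)

    def test_eval_time_too_early_rejected(self, balance):
        with pytest.raises(ValueError, match="too early"):
            assemble_spatial_profile(balance, TFParams(), eval_time=500.0)

    def test_mutual_exclusion_block(self, control_profile):
        """T/BRA-above-SOX2 positions form one contiguous caudal block."""
        T = control_profile.protein["tbra"]
        S = control_profile.protein["sox2"]
        ahead = np.nonzero(T > S)[0]
        assert len(ahead) > 0
        assert np.all(np.diff(ahead) == 1)   # one contiguous block
        assert ahead[0] <= 5                 # starting at the caudal end
        assert control_profile.x[ahead[-1]] < 1250.0

    def test_staggered_domain_order(self, control_domains):
        """Caudal-to-rostral onset order of the observable genes."""
        starts = {g: control_domains[g][0][0] for g in OBSERVABLE_GENES}
        assert starts["tbra"] < 100.0
        assert starts["pax6"] > 1000.0
        assert starts["ngn2"] > starts["pax6"]
        ends = {g: control_domains[g][-1][1] for g in OBSERVABLE_GENES}
        assert ends["tbra"] < ends["nkx12"] < ends["cdx4"]


def _triangle_profile():
    x = np.linspace(0, 2500, 251)
    tri = np.clip(1.0 - np.abs(x - 1000.0) / 500.0, 0.0, None)
    mrna = {g: np.zeros_like(x) for g in GENES}
    mrna["pax6"] = tri
    return TFProfile(x=x, eval_time=6000.0, mrna=mrna, protein={})


class TestDomains:
    def test_zero_gene_has_no_domain(self):
        domains = extract_domains(_triangle_profile())
        assert domains["tbra"] == []

    def test_triangle_bounded_by_threshold_crossings(self):
        domains = extract_domains(_triangle_profile(), threshold_fraction=0.5)
        (start, end), = domains["pax6"]
        assert start == pytest.approx(750.0, abs=1.0)
        assert end == pytest.approx(1250.0, abs=1.0)

    def test_reference_thresholds_report_collapse(self):
        prof = _triangle_profile()
        weak = _triangle_profile()
        weak.mrna["pax6"] = 0.01 * prof.mrna["pax6"]
        assert extract_domains(weak)["pax6"]  # self-normalised: still "on"
        assert extract_domains(weak, reference=prof)["pax6"] == []

    def test_sliver_and_gap_tidying(self):
        prof = _triangle_profile()
        y = np.zeros_like(prof.x)
        y[10:50] = 1.0
        y[51:53] = 1.0     # satellite across a 10-um gap: merged
        y[200] = 0.6       # isolated sub-grid sliver: dropped
        prof.mrna["pax6"] = y
        intervals = extract_domains(prof, threshold_fraction=0.5)["pax6"]
        assert len(intervals) == 1
        assert intervals[0][1] - intervals[0][0] > 400.0


def _domains(**kw):
    base = {
        "tbra": [(0.0, 400.0)],
        "sox2": [(0.0, 2500.0)],
        "nkx12": [(0.0, 700.0)],
        "cdx4": [(0.0, 1400.0)],
        "pax6": [(1300.0, 2500.0)],
        "ngn2": [(2200.0, 2500.0)],
    }
    base.update(kw)
    return base


class TestPatternVerdict:
    def test_staggered_layout(self):
        assert check_pattern(_domains()).verdict == "CORRECT_STAGGERED"

    def test_tbra_spread_is_overlapping(self):
        v = check_pattern(_domains(tbra=[(0.0, 1500.0)]))
        assert v.verdict == "OVERLAPPING"
        assert not (v.tbra_restricted and v.tbra_disjoint)

    def test_nkx12_invading_ngn2_is_overlapping(self):
        assert check_pattern(_domains(nkx12=[(0.0, 2300.0)])).verdict == "OVERLAPPING"

    def test_no_transition_zone_is_other(self):
        # Ngn2 lost entirely: stem markers stay put, but no staggering either
        assert check_pattern(_domains(ngn2=[])).verdict == "OTHER"

    def test_missing_gene_rejected(self):
        d = _domains()
        del d["ngn2"]
        with pytest.raises(KeyError):
            check_pattern(d)


def test_hill_constant_scaling_helpers():
    p = TFParams()
    scaled = p.scale_hill_constants(1.3)
    assert scaled.F_FT == pytest.approx(13.0)
    assert scaled.alpha_m == p.alpha_m
    only = p.scale_hill_constants(2.0, only=["S_ST"])
    assert only.S_ST == pytest.approx(4.0) and only.F_FT == p.F_FT
    uniform = p.with_uniform_hill_constants(20.0)
    assert all(getattr(uniform, n) == 20.0 for n in HILL_CONSTANT_NAMES)
    with pytest.raises(KeyError):
        p.scale_hill_constants(2.0, only=["alpha_m"])
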
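"""Transcritical/Hopf location, criticality sign, and orbit diagnostics."""

import numpy as np
import pytest

from triscav import (
    bifurcation_diagram,
    equilibrium_interior,
    first_lyapunov_sign,
    hopf_phi,
    jacobian,
    locate_hopf,
    locate_transcritical,
    orbit_classify,
)
from triscav.bifurcation import (
    BifurcationEvent,
    _cluster_1d,
    _directional_d2,
    _directional_d3,
)


class TestTranscritical:
    def test_beta_threshold(self, ds39):
        ev = locate_transcritical(ds39(nu1=0.069), "beta", (11.0, 14.0))
        assert ev.critical_value == pytest.approx(12.546517, abs=1e-4)
        assert np.allclose(ev.equilibrium[:2], [0.393409, 0.827479], atol=1e-5)

    def test_nu1_threshold(self, ds39):
        ev = locate_transcritical(ds39(nu1=0.05), "nu1", (0.05, 0.15))
        assert ev.critical_value == pytest.approx(0.097250, abs=1e-4)
        assert np.allclose(ev.equilibrium[:2], [0.420748, 0.797983], atol=1e-5)

    def test_defining_condition_holds_at_root(self, ds39):
        p = ds39(nu1=0.069)
        ev = locate_transcritical(p, "beta", (11.0, 14.0))
        x, y = ev.equilibrium[:2]
        assert abs(p.alpha * x + ev.critical_value * y - p.mu) < 1e-10

    @pytest.mark.parametrize(
        "nu1,param,bracket,expected_U",
        [
            (0.069, "beta", (11.0, 14.0), (-0.1595, -0.7806, 0.6043)),
            (0.05, "nu1", (0.05, 0.15), (-0.1970, -0.7605, 0.6188)),
        ],
    )
    def test_sotomayor_eigenvectors_and_conditions(
        self, ds39, nu1, param, bracket, expected_U
    ):
        ev = locate_transcritical(ds39(nu1=nu1), param, bracket)
        d = ev.diagnostics
        U = d["U"]
        assert np.allclose(np.abs(U), np.abs(expected_U), atol=1e-2)
        assert d["Delta1"] == 0.0
        assert d["Delta2"] != 0.0 and d["Delta3"] != 0.0
        assert d["is_transcritical"]
        # Delta2 is the printed closed form ybar * u3
        assert d["Delta2"] == pytest.approx(ev.equilibrium[1] * U[2], abs=1e-12)

    def test_no_sign_change_raises(self, ds39):
        with pytest.raises(ValueError, match="sign"):
            locate_transcritical(ds39(nu1=0.069), "beta", (11.0, 11.5))

    def test_scavenger_branch_exchange(self, ds39):
        """Past the threshold a strictly interior equilibrium appears."""
        p = ds39(nu1=0.069)
        ev = locate_transcritical(p, "beta", (11.0, 14.0))
        below = equilibrium_interior(p.replace(beta=ev.critical_value - 0.2), seed=0)
        above = equilibrium_interior(p.replace(beta=ev.critical_value + 0.2), seed=0)
        assert below == []
        assert len(above) >= 1 and above[0].z > 0


class TestHopf:
    def test_liu_root_in_nu1(self, ds39):
        ev = locate_hopf(ds39(), "nu1", (0.05, 0.09), seed=0)
        assert ev.critical_value == pytest.approx(0.0675, abs=5e-4)
        assert ev.diagnostics["rho1"] == pytest.approx(0.3805, abs=1e-3)
        assert ev.diagnostics["rho3"] == pytest.approx(0.0649, abs=1e-3)
        assert ev.diagnostics["dphi_dparam"] == pytest.approx(0.2155, abs=5e-3)

    def test_conjugate_pair_on_axis_at_root(self, ds39):
        p = ds39()
        ev = locate_hopf(p, "nu1", (0.05, 0.09), seed=0)
        pv = p.replace(nu1=ev.critical_value)
        eigs = np.linalg.eigvals(jacobian(ev.equilibrium, pv))
        pair = sorted(eigs, key=lambda e: abs(e.imag))[1:]
        assert max(abs(e.real) for e in pair) < 1e-6
        assert pair[0].imag != 0

    def test_phi_values_off_the_root(self, ds39):
        phi, rho1, rho2, rho3 = hopf_phi(ds39(nu1=0.07), seed=0)
        assert phi == pytest.approx(0.0061, abs=5e-4)
        phi_h, *_ = hopf_phi(ds39(nu1=0.0675), seed=0)
        assert abs(phi_h) < 5e-4

    def test_hopf_in_handling_time_parameter(self, ds39):
        ev = locate_hopf(ds39(nu1=0.069), "A1", (0.1, 0.2), seed=0)
        assert ev.critical_value == pytest.approx(0.122553, abs=1e-3)
        assert np.allclose(
            ev.equilibrium, [0.389404, 0.799242, 0.023228], atol=1e-3
        )

    def test_root_is_simple(self, ds39):
        ev = locate_hopf(ds39(), "nu1", (0.05, 0.09), seed=0)
        assert abs(ev.diagnostics["dphi_dparam_branch"]) > 0.1


class TestFirstLyapunov:
    def test_normal_form_oracle(self):
        """The projection pipeline recovers the sign of the cubic coefficient
        of the planar Hopf normal form embedded in 3-d."""
        A = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, -1]])
        q = np.array([1.0, -1j, 0])
        pvec = np.array([1.0, -1j, 0])
        pvec = pvec / np.conj(np.vdot(pvec, q))
        for sigma in (-1.0, 1.0):

            def F(u, s=sigma):
                x, y, z = u
                r2 = x * x + y * y
                return np.array([-y + s * x * r2, x + s * y * r2, -z])

            x0 = np.zeros(3, dtype=complex)
            qb = np.conj(q)
            c1 = np.vdot(pvec, _directional_d3(F, x0, q, q, qb))
            s_vec = np.linalg.solve(A, _directional_d2(F, x0, q, qb))
            c2 = -2.0 * np.vdot(pvec, _directional_d2(F, x0, q, s_vec))
            M = 2j * np.eye(3) - A
            r = np.linalg.solve(M, _directional_d2(F, x0, q, q))
            c3 = np.vdot(pvec, _directional_d2(F, x0, qb, r))
            l1 = float(np.real(c1 + c2 + c3) / 2.0)
            assert l1 == pytest.approx(4.0 * sigma, rel=1e-3)

    def test_supercritical_at_reference_hopf(self, ds39):
        ev = locate_hopf(ds39(), "nu1", (0.05, 0.09), seed=0)
        sign, l1 = first_lyapunov_sign(ev, ds39())
        assert sign == -1 and l1 < 0

    def test_small_stable_cycle_past_the_hopf(self, ds39):
        """Supercriticality corroborated by simulation: just below nu1^H a
        small-amplitude attracting cycle exists, and it shrinks toward the
        Hopf point."""
        s_far = orbit_classify(
            ds39(nu1=0.060), transient=2000.0, sample_window=600.0
        )
        s_near = orbit_classify(
            ds39(nu1=0.066), transient=2000.0, sample_window=600.0
        )
        assert s_near.attractor_type == "periodic-1"
        assert s_far.attractor_type == "periodic-1"
        assert 0 < s_near.amplitude < s_far.amplitude


class TestOrbitClassification:
    def test_cluster_helper_counts_gaps(self):
        vals = np.array([1.0, 1.0002, 2.0, 2.0001, 3.5])
        labels, n = _cluster_1d(vals, tol=1e-3)
        assert n == 3
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_equilibrium_regime(self, ds39):
        s = orbit_classify(ds39(nu1=0.097), transient=1500.0, sample_window=500.0)
        assert s.attractor_type == "equilibrium"
        assert s.amplitude < 1e-3

    def test_detector_consistency_near_hopf(self, ds39):
        """The orbit detector flips equilibrium -> periodic within +-0.002
        of the Liu-criterion Hopf value."""
        ev = locate_hopf(ds39(), "nu1", (0.05, 0.09), seed=0)
        above = orbit_classify(
            ds39(nu1=ev.critical_value + 0.002),
            transient=4000.0, sample_window=800.0,
        )
        below = orbit_classify(
            ds39(nu1=ev.critical_value - 0.002),
            transient=4000.0, sample_window=800.0,
        )
        assert above.attractor_type == "equilibrium"
        assert below.attractor_type.startswith("periodic")

    def test_diagram_scan_structure(self, ds39):
        grid = [0.045, 0.07, 0.097]
        df = bifurcation_diagram(
            ds39(), "nu1", grid, transient=1500.0, sample_window=500.0
        )
        assert list(df["param_value"]) == grid
        assert df.loc[0, "attractor_type"] == "periodic-1"
        assert df.loc[2, "attractor_type"] == "equilibrium"
        assert (df["error"] == "").all()

    def test_holling_type_ii_reduction_is_stable_at_low_harvesting(self, ds39):
        # dropping the joint-interference term (A3 = 0) removes the chaotic
        # window: the system is already stable at nu1 = 0.03
        s = orbit_classify(
            ds39(nu1=0.03, A3=0.0), transient=2000.0, sample_window=600.0
        )
        assert s.attractor_type == "equilibrium"
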
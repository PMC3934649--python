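"""BED, BEEUD, TCP and NTCP model behaviour."""

import math

import numpy as np
import pytest

from brachyeval import (
    FractionationParams,
    NTCPParams,
    PlanParams,
    TCPParams,
    bed,
    beeud_region,
    evaluate_plan,
    load_parameter_file,
    ntcp,
    partition_regions,
    quality_indices,
    tcp,
    tcp_uniform,
    threshold_volumes,
    voxelwise_tcp_oracle,
)
from brachyeval.radiobiology import bed_from_axis
from brachyeval.synthetic import (
    generate_cold_normal_dvh,
    generate_ideal_implant_dvh,
    random_dvh,
)

ALPHA = 0.3
FX = FractionationParams(alpha=ALPHA, alpha_beta=10.0, n_fractions=4)
FX_PHYS = FractionationParams(alpha=ALPHA, alpha_beta=10.0, n_fractions=1, G=0.0)


def region_tcp_from_dvh(dvh, normal, Dref, rho, fx, alpha):
    """Full region pipeline: partition → BEEUD → weighted TCP."""
    part = partition_regions(dvh, Dref, "target")
    tv = threshold_volumes(dvh, normal, Dref)
    qi = quality_indices(tv)
    beeuds = [
        None if not reg else beeud_region([(d / 100.0, v) for d, v in reg],
                                          fx, alpha)
        for reg in part.regions
    ]
    value = tcp(TCPParams(rho=rho, TV_Dref=tv.TV_Dref, qi=qi, beeud=beeuds),
                alpha)
    frags = [(d / 100.0, v) for reg in part.regions for d, v in reg]
    return value, frags


class TestBED:
    def test_g_zero_reduces_to_physical_dose(self):
        fx = FractionationParams(alpha=ALPHA, alpha_beta=3.0, n_fractions=5,
                                 G=0.0)
        assert bed(35.0, 7.0, fx) == 35.0

    def test_single_fraction_example(self):
        fx = FractionationParams(alpha=ALPHA, alpha_beta=10.0, n_fractions=1)
        assert bed(10.0, 10.0, fx) == pytest.approx(20.0)

    def test_random_matches_arithmetic_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 10))
            d = float(rng.uniform(0.5, 12.0))
            ab = float(rng.uniform(1.0, 15.0))
            g = float(rng.uniform(0.0, 1.0))
            fx = FractionationParams(alpha=ALPHA, alpha_beta=ab, n_fractions=n,
                                     G=g)
            expected = n * d * (1.0 + g * d / ab)
            assert bed(None, d, fx) == pytest.approx(expected, rel=1e-12)

    def test_linear_growth_in_dose_per_fraction(self):
        fx = FractionationParams(alpha=ALPHA, alpha_beta=10.0, n_fractions=1)
        d = np.array([2.0, 4.0, 6.0])
        excess = bed_from_axis(d, fx) - d          # = d²/(α/β)
        np.testing.assert_allclose(excess, d**2 / 10.0, rtol=1e-12)

    def test_inconsistent_doses_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            bed(30.0, 7.0, FX)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            bed(-1.0, None, FX)

    def test_dose_scope_total(self):
        fx = FractionationParams(alpha=ALPHA, alpha_beta=10.0, n_fractions=4,
                                 dose_scope="total")
        # axis value 28 Gy whole course → d = 7 Gy/fraction
        assert bed_from_axis(np.array([28.0]), fx)[0] == pytest.approx(
            28.0 * (1 + 7.0 / 10.0))


class TestBEEUD:
    def test_uniform_region_equals_its_bed(self):
        subs = [(5.0, 1.0), (5.0, 2.5), (5.0, 0.3)]
        expected = bed(None, 5.0, FX)
        assert beeud_region(subs, FX, ALPHA) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_single_subvolume(self):
        assert beeud_region([(7.0, 2.0)], FX, ALPHA) == pytest.approx(
            bed(None, 7.0, FX), rel=1e-12)

    def test_two_equal_subvolumes_closed_form(self):
        # physical-dose BEDs 10 and 20 Gy at α=0.3:
        # −(1/0.3)·ln[(e⁻³+e⁻⁶)/2] = 12.148532763287346 Gy
        value = beeud_region([(10.0, 1.0), (20.0, 1.0)], FX_PHYS, ALPHA)
        assert value == pytest.approx(12.148532763287346, rel=1e-12)

    def test_bounded_by_region_bed_extremes(self, rng):
        for _ in range(20):
            subs = [(float(rng.uniform(0.5, 12.0)), float(rng.uniform(0.1, 5)))
                    for _ in range(int(rng.integers(1, 12)))]
            beds = bed_from_axis(np.array([d for d, _ in subs]), FX)
            val = beeud_region(subs, FX, ALPHA)
            assert beds.min() - 1e-9 <= val <= beds.max() + 1e-9

    def test_jensen_bound_cold_spots_dominate(self, rng):
        for _ in range(20):
            subs = [(float(rng.uniform(0.5, 12.0)), float(rng.uniform(0.1, 5)))
                    for _ in range(10)]
            beds = bed_from_axis(np.array([d for d, _ in subs]), FX)
            vols = np.array([v for _, v in subs])
            mean_bed = float(np.sum(beds * vols) / vols.sum())
            assert beeud_region(subs, FX, ALPHA) <= mean_bed + 1e-9

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            beeud_region([], FX, ALPHA)


class TestTCP:
    def test_no_clonogens_gives_certain_control(self):
        qi = quality_indices_stub()
        assert tcp(TCPParams(rho=0.0, TV_Dref=40.0, qi=qi,
                             beeud=[10.0, 20.0, 25.0, 30.0]), ALPHA) == 1.0

    def test_ideal_implant_collapses_to_uniform_formula(self):
        # uniform dose: region 2 only → TCP = exp[−ρ·V·e^(−α·BED)]
        from brachyeval.indices import QualityIndices

        qi = QualityIndices(CI=1.0, EI=0.0, DHI=1.0, ODI=0.0, DNR=0.0)
        rho, V, b = 0.05, 42.0, 30.0
        got = tcp(TCPParams(rho=rho, TV_Dref=V, qi=qi,
                            beeud=[None, b, None, None]), ALPHA)
        assert got == pytest.approx(tcp_uniform(rho, V, ALPHA, b), rel=1e-12)

    def test_equals_voxelwise_oracle_on_random_dvhs(self, rng):
        for _ in range(50):
            dvh = random_dvh(rng, n_bins=int(rng.integers(5, 40)))
            normal = random_dvh(rng, label="normal")
            rho = float(10 ** rng.uniform(-3, 0))
            value, frags = region_tcp_from_dvh(dvh, normal, 400.0, rho, FX,
                                               ALPHA)
            oracle = voxelwise_tcp_oracle(frags, rho, FX, ALPHA)
            assert np.isclose(value, oracle, rtol=1e-9, atol=1e-300)

    def test_monotone_in_each_region_beeud(self):
        from brachyeval.indices import QualityIndices

        qi = QualityIndices(CI=0.8, EI=0.1, DHI=0.6, ODI=0.1, DNR=0.4)
        base = [5.0, 20.0, 30.0, 40.0]
        ref = tcp(TCPParams(rho=0.05, TV_Dref=40.0, qi=qi, beeud=base), ALPHA)
        for r in range(4):
            bumped = list(base)
            bumped[r] += 5.0
            assert tcp(TCPParams(rho=0.05, TV_Dref=40.0, qi=qi,
                                 beeud=bumped), ALPHA) >= ref

    def test_no_coverage_rejected(self):
        from brachyeval.indices import QualityIndices

        qi = QualityIndices(CI=0.0, EI=0.0, DHI=0.0, ODI=0.0, DNR=0.0)
        with pytest.raises(ValueError, match="no target coverage"):
            tcp(TCPParams(rho=0.05, TV_Dref=0.0, qi=qi,
                          beeud=[5.0, None, None, None]), ALPHA)


class TestTCPUniform:
    def test_limits(self):
        assert tcp_uniform(0.0, 50.0, ALPHA, 10.0) == 1.0
        assert tcp_uniform(1.0, 0.0, ALPHA, 10.0) == 1.0
        assert tcp_uniform(1.0, 1.0, ALPHA, 1e9) == pytest.approx(1.0)

    def test_unit_survival_case(self):
        # ρ·V = 1 surviving clonogen on average at zero dose → TCP = e⁻¹
        assert tcp_uniform(1.0, 1.0, ALPHA, 0.0) == pytest.approx(math.exp(-1))

    def test_monotone_in_bed(self):
        vals = [tcp_uniform(0.1, 50.0, ALPHA, b) for b in (0, 10, 20, 40, 80)]
        assert np.all(np.diff(vals) > 0)


class TestVoxelwiseOracle:
    def test_single_subvolume_equals_uniform(self):
        assert voxelwise_tcp_oracle([(10.0, 3.0)], 0.2, FX, ALPHA) == (
            pytest.approx(tcp_uniform(0.2, 3.0, ALPHA, bed(None, 10.0, FX)),
                          rel=1e-12))

    def test_zero_density_gives_one(self):
        assert voxelwise_tcp_oracle([(5.0, 1.0)], 0.0, FX, ALPHA) == 1.0


class TestNTCP:
    def test_as_printed_hand_arithmetic(self):
        # k=1, N0=e, TV=V0=V_normal=1, EI=0, BEEUDn1=0:
        # NTCPF = exp[e⁻¹·1·1] = 1.444667861009766, outside [0,1] → warning
        params = NTCPParams(N0=math.e, k=1.0, V0=1.0, TV=1.0, V_normal=1.0,
                            EI=0.0, beeud_n=[0.0, None], variant="as_printed")
        res = ntcp(params, ALPHA)
        assert res.value == pytest.approx(1.444667861009766, rel=1e-12)
        assert res.warnings  # literal form exceeds 1 and must say so

    def test_zero_volume_literal_case(self):
        params = NTCPParams(N0=2.0, k=1.5, V0=1.0, TV=1.0, V_normal=0.0,
                            EI=0.0, beeud_n=[None, None], variant="as_printed")
        assert ntcp(params, ALPHA).value == 1.0

    def test_sign_corrected_is_probability_and_saturates(self):
        common = dict(N0=5.0, k=1.5, V0=50.0, TV=40.0, V_normal=80.0, EI=0.2,
                      variant="sign_corrected")
        vals = []
        for b in (1.0, 10.0, 50.0, 500.0, 5e4):
            res = ntcp(NTCPParams(beeud_n=[b, b], **common), ALPHA)
            assert 0.0 < res.value <= 1.0
            assert not res.warnings
            vals.append(res.value)
        assert np.all(np.diff(vals) >= 0)           # monotone in BEEUD
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)  # total depletion

    def test_as_printed_out_of_range_always_warns(self, rng):
        for _ in range(20):
            params = NTCPParams(
                N0=float(rng.uniform(0.5, 20)), k=float(rng.uniform(0.5, 3)),
                V0=float(rng.uniform(10, 100)), TV=float(rng.uniform(10, 80)),
                V_normal=float(rng.uniform(20, 150)),
                EI=float(rng.uniform(0, 0.5)),
                beeud_n=[float(rng.uniform(1, 40)), float(rng.uniform(5, 80))],
                variant="as_printed")
            res = ntcp(params, ALPHA)
            if not 0.0 <= res.value <= 1.0:
                assert res.warnings

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NTCPParams(N0=1.0, k=0.0, V0=1.0, TV=1.0, V_normal=1.0, EI=0.0,
                       beeud_n=[1.0, 1.0])
        with pytest.raises(ValueError, match="N0"):
            ntcp(NTCPParams(N0=0.0, k=1.0, V0=1.0, TV=1.0, V_normal=1.0,
                            EI=0.1, beeud_n=[1.0, 1.0], variant="as_printed"),
                 ALPHA)


class TestEvaluatePlan:
    def _params(self, **kw):
        defaults = dict(Dref=400.0, alpha=ALPHA, alpha_beta=10.0, rho=0.05,
                        n_fractions=4, N0=5.0, k=1.5, V0=50.0,
                        ntcp_variant="sign_corrected")
        defaults.update(kw)
        return PlanParams(**defaults)

    def test_ideal_plan_with_zero_density_gives_certain_control(self):
        target = generate_ideal_implant_dvh(50.0, 400.0)
        normal = generate_cold_normal_dvh(100.0, 400.0)
        result = evaluate_plan(target, {"rectum": normal}, self._params(rho=0.0))
        assert result.tcp == 1.0
        qi = result.qi["rectum"]
        assert (qi.CI, qi.EI, qi.DHI, qi.ODI, qi.DNR) == (1, 0, 1, 0, 0)

    def test_as_printed_warning_is_surfaced(self, rng):
        target = random_dvh(rng)
        normal = random_dvh(rng, label="rectum")
        result = evaluate_plan(target, {"rectum": normal},
                               self._params(ntcp_variant="as_printed", N0=2.0))
        if not 0.0 <= result.ntcp_per_organ["rectum"] <= 1.0:
            assert any("rectum" in w for w in result.warnings)

    def test_each_organ_evaluated_independently(self, rng):
        target = random_dvh(rng)
        rectum = random_dvh(rng, label="rectum")
        bladder = random_dvh(rng, label="bladder")
        both = evaluate_plan(target, {"rectum": rectum, "bladder": bladder},
                             self._params())
        solo = evaluate_plan(target, {"bladder": bladder}, self._params())
        assert both.ntcp_per_organ["bladder"] == pytest.approx(
            solo.ntcp_per_organ["bladder"], rel=1e-12)


class TestParameterFile:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "params.txt"
        p.write_text(
            "# evaluation parameters\n"
            "Dref = 400\nalpha = 0.3\nalpha_beta = 10\nrho = 1e6\n"
            "n_fractions = 4\nG = 1.0\nN0 = 5\nk = 1.5\nV0 = 50\n"
            "dose_scope = per_fraction\nntcp_variant = sign_corrected\n"
        )
        params = load_parameter_file(str(p))
        assert params.Dref == 400.0
        assert params.rho == 1e6
        assert params.ntcp_variant == "sign_corrected"

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "params.txt"
        p.write_text("Dref = 400\nalpha = 0.3\nalpha_beta = 10\nrho = 1\n"
                     "bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_parameter_file(str(p))

    def test_missing_required_rejected(self, tmp_path):
        p = tmp_path / "params.txt"
        p.write_text("alpha = 0.3\n")
        with pytest.raises(ValueError, match="missing required"):
            load_parameter_file(str(p))


def quality_indices_stub():
    from brachyeval.indices import QualityIndices

    return QualityIndices(CI=0.9, EI=0.1, DHI=0.7, ODI=0.05, DNR=0.3)
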
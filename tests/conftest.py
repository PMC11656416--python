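import pytest

import nmrpka as n


def analyze_scenario(name: str, seed: int = 1, noise_shift_sd: float = 0.0,
                     noise_integral_rel_sd: float = 0.0):
    """Simulate a named scenario and push it through the analysis pipeline.

    Returns (scenario, simulation, pointset, linear fit).
    """
    sc = n.scenario(
        name,
        seed=seed,
        noise_shift_sd=noise_shift_sd,
        noise_integral_rel_sd=noise_integral_rel_sd,
    )
    sim = n.simulate_tube(sc.system)
    ctx = n.IonicContext(
        strong_cations=sc.system.strong_cations,
        strong_anions=sc.system.strong_anions,
        analyte=sc.system.analyte,
    )
    ps = n.build_points(sim.measurements, sc.system.indicator, sc.system.reference, ctx)
    fit = n.fit_linear(ps.points, analyte_dz2=sc.analyte_dz2)
    return sc, sim, ps, fit


@pytest.fixture(scope="session")
def boric_noise_free():
    """Noise-free boric acid / 2-methylimidazole gradient, fully analyzed."""
    return analyze_scenario("boric_acid")


@pytest.fixture(scope="session")
def benzoic_no_coions():
    """Noise-free benzoic acid / acetate gradient without any strong co-ions.

    The charge-balance identity kappa = deprotonated analyte is exact (up to
    hydroxide) only in this composition.
    """
    sys = n.TubeSystem(
        analyte=n.AcidSpecies("benzoic acid", (4.20,), 0.010, 0),
        indicator=n.INDICATORS["acetate"],
        source_conc_C0=0.050,
        noise_shift_sd=0.0,
        noise_integral_rel_sd=0.0,
        seed=0,
    )
    return sys, n.simulate_tube(sys)
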
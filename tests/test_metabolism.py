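"""Expression, kinetics, integration oracles, score and toxicity."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from evocross.config import OdeConfig
from evocross.fixtures import two_gene_genome
from evocross.genome import Genome, GenomicUnit, random_genome
from evocross.metabolism import (CellState, OdeSystem, ProteinSpecies, build_ode,
                                 express, integrate_time_step, is_essential,
                                 score, toxicity_exceeded)


def make_cell(n_proteins, max_tag=12, internal=None, external=None, proteins=None):
    cell = CellState(
        proteins=np.zeros(n_proteins) if proteins is None else np.asarray(proteins, float),
        internal=np.zeros(max_tag),
        external_local=np.zeros(max_tag))
    for tag, v in (internal or {}).items():
        cell.internal[tag - 1] = v
    for tag, v in (external or {}).items():
        cell.external_local[tag - 1] = v
    return cell


def reference_trajectory(species, cell, t_total, phi=0.1):
    """Independent oracle: per-copy (unmerged) RHS integrated by scipy LSODA.

    State: [per-copy proteins | internal | external], dense over the cell's
    tag universe.  Includes per-tag uptake/production/release accumulators.
    """
    n = len(species)
    mt = cell.max_tag
    y0 = np.concatenate([cell.proteins, cell.internal, cell.external_local,
                         np.zeros(3 * mt)])

    def rhs(t, y):
        dy = np.zeros_like(y)
        for j, sp in enumerate(species):
            dy[j] = sp.beta - phi * y[j]
        for j, sp in enumerate(species):
            kc = abs(sp.kcat)
            if sp.s == sp.p:  # pump
                if sp.kcat > 0:
                    sub, prod = n + mt + sp.s - 1, n + sp.s - 1
                    acc = n + 2 * mt + sp.s - 1
                else:
                    sub, prod = n + sp.s - 1, n + mt + sp.s - 1
                    acc = n + 4 * mt + sp.s - 1
            else:
                sub, prod = n + sp.s - 1, n + sp.p - 1
                acc = n + 3 * mt + sp.p - 1
            s_conc = max(y[sub], 0.0)
            flux = kc * y[j] * s_conc / (sp.km + s_conc)
            dy[sub] -= flux
            dy[prod] += flux
            dy[acc] += flux
        return dy

    sol = solve_ivp(rhs, (0.0, t_total), y0, method="LSODA",
                    rtol=1e-12, atol=1e-14, dense_output=False)
    assert sol.success
    yf = sol.y[:, -1]
    return {
        "proteins": yf[:n],
        "internal": yf[n:n + mt],
        "external": yf[n + mt:n + 2 * mt],
        "uptake": yf[n + 2 * mt:n + 3 * mt],
        "production": yf[n + 3 * mt:n + 4 * mt],
        "release": yf[n + 4 * mt:n + 5 * mt],
    }


# -- expression -----------------------------------------------------------------


def test_express_worked_two_gene_system():
    species = express(two_gene_genome())
    assert len(species) == 2
    pump, enz = species
    assert pump.is_pump and pump.direction == "in" and pump.s == 10
    assert not enz.is_pump and (enz.s, enz.p) == (10, 7)
    # beta comes in full from the region's promoter; KM is derived
    assert pump.beta == enz.beta == 0.08
    assert enz.km == pytest.approx(abs(enz.kcat) / 1e-3)


def test_express_requires_promoter(rng):
    g = random_genome(rng, 3, 0, 1)  # one E, no P
    assert express(g) == []


def test_express_operon_members_share_promoter_beta():
    g = Genome.from_units([
        GenomicUnit("P", 0.33, 1, 1, 0.01, 1e-4),
        GenomicUnit("E", 0.9, 4, 5, 0.01, 1e-4),   # own beta attribute is silent
        GenomicUnit("E", 0.1, 5, 6, 0.01, 1e-4),
    ])
    assert [sp.beta for sp in express(g)] == [0.33, 0.33]


# -- essentiality ------------------------------------------------------------------


@pytest.mark.parametrize("tag,expected", [(2, True), (3, True), (7, True),
                                          (10, False), (1, False), (9, False)])
def test_is_essential(tag, expected):
    assert is_essential(tag) is expected


def test_is_essential_rejects_nonpositive():
    with pytest.raises(ValueError):
        is_essential(0)


# -- ODE structure ------------------------------------------------------------------


def test_two_gene_ode_matches_written_equations():
    """The worked importer/converter system reduces to exactly five coupled
    equations whose right-hand sides match the written Michaelis-Menten form."""
    species = express(two_gene_genome())
    pump, enz = species
    cell = make_cell(2, external={10: 10.0})
    ode = build_ode(species, cell, OdeConfig())
    rng = np.random.default_rng(5)
    for _ in range(20):
        y = np.zeros(ode.n_state)
        y[:2] = rng.uniform(0, 2, 2)                      # [Pump], [Enzyme]
        y[2:ode.n_pools] = rng.uniform(0, 5, ode.n_pools - 2)
        dy = ode.derivative(y)
        phi = ode.config.phi
        pump_c, enz_c = y[0], y[1]
        i7, i10 = y[2], y[3]       # internal active tags sorted: 7, 10
        e7, e10 = y[4], y[5]       # external active tags
        vp = pump.kcat * pump_c * e10 / (pump.km + e10)
        ve = enz.kcat * enz_c * i10 / (enz.km + i10)
        assert dy[0] == pytest.approx(pump.beta - phi * pump_c)
        assert dy[1] == pytest.approx(enz.beta - phi * enz_c)
        assert dy[3] == pytest.approx(vp - ve)            # d[#10 internal]
        assert dy[2] == pytest.approx(ve)                 # d[#7 internal]
        assert dy[5] == pytest.approx(-vp)                # d[#10 external]
        assert dy[4] == 0.0                               # external #7 untouched


def test_no_proteins_means_no_dynamics():
    cell = make_cell(0, internal={3: 1.5}, external={10: 2.0})
    ode = build_ode([], cell, OdeConfig())
    out = integrate_time_step(ode, cell)
    assert np.array_equal(out.internal, cell.internal)
    assert np.array_equal(out.external_local, cell.external_local)


def test_metabolite_derivatives_sum_to_zero(rng):
    """Enzymes transform 1:1 and pumps translocate, so total metabolite mass
    has zero derivative for any genome and any state."""
    for _ in range(30):
        g = random_genome(rng, 30, 8, 12)
        species = express(g)
        cell = make_cell(len(species))
        ode = build_ode(species, cell, OdeConfig())
        y = rng.uniform(0, 3, ode.n_state)
        dy = ode.derivative(y)
        pools = dy[ode.n_groups:ode.n_pools]
        assert abs(pools.sum()) < 1e-12


# -- integration oracles ---------------------------------------------------------------


def test_protein_closed_form():
    beta, phi = 0.08, 0.1
    g = two_gene_genome(beta, beta)
    species = express(g)
    cell = make_cell(2)  # no external resource: protein dynamics only
    cfg = OdeConfig()
    out = integrate_time_step(build_ode(species, cell, cfg), cell)
    expected = beta / phi * (1 - math.exp(-phi * cfg.centi_steps))
    assert out.proteins == pytest.approx([expected, expected], rel=10 * cfg.rel_tol)
    assert expected == pytest.approx(0.79996, abs=1e-5)


def test_protein_closed_form_random_initials(rng):
    phi = 0.1
    for _ in range(100):
        beta, e0 = rng.uniform(0, 1), rng.uniform(0, 10)
        sp = ProteinSpecies(0, beta, 2, 3, 0.01, 100.0)
        cell = make_cell(1, proteins=[e0])
        cfg = OdeConfig()
        out = integrate_time_step(build_ode([sp], cell, cfg), cell)
        expected = beta / phi + (e0 - beta / phi) * math.exp(-phi * cfg.centi_steps)
        assert out.proteins[0] == pytest.approx(expected, rel=10 * cfg.rel_tol, abs=1e-12)


def test_integration_matches_reference_integrator(rng):
    """Cash-Karp at default tolerances vs scipy LSODA at 1e-12 on the worked
    two-gene system: concentrations agree to < 1e-6 ACU."""
    species = express(two_gene_genome())
    cell = make_cell(2, external={10: 10.0}, internal={10: 0.2})
    cfg = OdeConfig()
    out = integrate_time_step(build_ode(species, cell, cfg), cell)
    ref = reference_trajectory(species, cell, float(cfg.centi_steps))
    assert np.max(np.abs(out.internal - ref["internal"])) < 1e-6
    assert np.max(np.abs(out.external_local - ref["external"])) < 1e-6
    assert np.max(np.abs(out.proteins - ref["proteins"])) < 1e-6


def test_merged_species_match_per_copy_reference(rng):
    """Gene copies are merged for integration (flux additivity); the result
    must match an unmerged per-copy reference integration."""
    base = express(two_gene_genome())
    # two identical pump copies with distinct concentrations + the enzyme
    species = [base[0], ProteinSpecies(**{**base[0].__dict__}), base[1]]
    cell = make_cell(3, external={10: 10.0}, proteins=[0.1, 0.9, 0.3])
    cfg = OdeConfig()
    ode = build_ode(species, cell, cfg)
    assert ode.n_groups == 2  # the two pump copies merged
    out = integrate_time_step(ode, cell)
    ref = reference_trajectory(species, cell, float(cfg.centi_steps))
    assert np.max(np.abs(out.internal - ref["internal"])) < 1e-6
    assert np.max(np.abs(out.proteins - ref["proteins"])) < 1e-6


def test_flux_accumulators_match_reference(rng):
    species = express(two_gene_genome())
    cell = make_cell(2, external={10: 10.0})
    cfg = OdeConfig()
    out = integrate_time_step(build_ode(species, cell, cfg), cell)
    ref = reference_trajectory(species, cell, float(cfg.centi_steps))
    assert np.max(np.abs(out.uptake - ref["uptake"])) < 1e-6
    assert np.max(np.abs(out.production - ref["production"])) < 1e-6
    assert np.max(np.abs(out.release - ref["release"])) < 1e-6


def test_zero_order_limit():
    """At [s] = 1e4 KM the consumption rate equals kcat*[E] within 0.1%."""
    kcat, ratio = 0.01, 1e-4
    km = kcat / ratio  # 100
    e0 = 5.0
    sp = ProteinSpecies(0, beta=0.1 * e0, s=4, p=6, kcat=kcat, km=km)  # beta=phi*E0
    s0 = 1e4 * km
    cell = make_cell(1, max_tag=6, internal={4: s0}, proteins=[e0])
    cfg = OdeConfig(centi_steps=10)
    out = integrate_time_step(build_ode([sp], cell, cfg), cell)
    rate = (s0 - out.internal[3]) / cfg.centi_steps
    assert rate == pytest.approx(kcat * e0, rel=1e-3)


def test_mass_conservation_random_systems(rng):
    for _ in range(20):
        g = random_genome(rng, 25, 6, 10)
        species = express(g)
        cell = make_cell(len(species), internal={2: 0.5, 5: 0.3},
                         external={10: 4.0, 3: 1.0})
        total0 = cell.internal.sum() + cell.external_local.sum()
        out = integrate_time_step(build_ode(species, cell, OdeConfig()), cell)
        total1 = out.internal.sum() + out.external_local.sum()
        assert total1 == pytest.approx(total0, rel=1e-9, abs=1e-9)
        assert np.all(out.internal >= 0) and np.all(out.external_local >= 0)


# -- score and toxicity ------------------------------------------------------------------


def test_score_sums_prime_tags():
    cell = make_cell(0, internal={2: 0.1, 3: 0.2, 4: 0.5})
    assert score(cell) == pytest.approx(0.3)


def test_score_empty_is_zero():
    assert score(make_cell(0)) == 0.0


def test_score_monotone_in_essential_concentration(rng):
    cell = make_cell(0, internal={7: 0.4, 4: 1.0})
    s0 = score(cell)
    cell.internal[6] += 0.2
    assert score(cell) > s0


@pytest.mark.parametrize("internal,expected", [
    ({10: 0.999}, False), ({10: 1.0}, True), ({}, False), ({4: 2.0}, True),
])
def test_toxicity_threshold(internal, expected):
    cell = make_cell(0, internal=internal)
    assert toxicity_exceeded(cell, 1.0) is expected


def test_toxicity_requires_positive_threshold():
    with pytest.raises(ValueError):
        toxicity_exceeded(make_cell(0), 0.0)
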
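"""Synthetic study generator: networks, tracer experiments, cultures, arrays.

Every stage of the analysis is exercised end to end on data with the same
statistical structure the estimators assume:

* MIDs are simulated from a ground-truth flux distribution through the EMU
  machinery, with additive Gaussian noise per mass channel (clipped at zero
  and renormalized) — matching the SD-weighted least-squares model.
* Culture time courses integrate dX/dt = mu*X, d[glc]/dt = -nu*X,
  d[ace]/dt = rho*X on a sampling grid, with optional multiplicative noise.
* Expression tables are log-normal signals in which designated gene sets
  receive a log2 shift between the two conditions; some genes belong to
  both the central-metabolism and AbrB sets to exercise the exclusion rule.

Default parameters mirror a glucose minimal-medium batch culture of a
genome-reduced *B. subtilis* strain (growth rate 0.46 1/h, glucose uptake
5.9, acetate production 2.7, succinate production 0.2 mmol/g-DCW/h).  All
generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atom_network import FluxVector, MetabolicNetwork, parse_network
from .emu import EMU, InputLabeling, decompose, simulate_mids
from .expression import ExpressionTable
from .flux_fit import PrecursorDemand
from .measurements import FragmentDef, MeasuredMID, map_fragment_to_emus, predict_fragment_mid
from .rates import TimeCourse

__all__ = [
    "SyntheticScenario",
    "make_network",
    "make_scenario",
    "simulate_measurements",
    "simulate_expression",
    "NETWORK_PRESETS",
]

# Two-carbon toy: one uptake, a two-branch split with a positional swap, one
# cleavage into two measurable one-carbon products.
TOY1_TEXT = """\
met Aex 2 substrate
met A 2 balanced
met B 2 balanced
met C 1 balanced
met D 1 balanced
met Cex 1 sink
met Dex 1 sink
upt: Aex (ab) -> A (ab)
v1: A (ab) -> B (ab)
v3: A (ab) -> B (ba)
v2: B (ab) -> C (a) + D (b)
out_c: C (a) -> Cex (a)
out_d: D (b) -> Dex (b)
"""

# Branched mimic of central metabolism: glycolysis-like A->B (reversible,
# with a positional swap), a decarboxylating PPP-like branch, pyruvate-
# dehydrogenase-like decarboxylation, acetate overflow, an anaplerotic
# carboxylation refilling B from C + unlabeled CO2 (this second producer of
# B is what makes the emp exchange flux observable in the MIDs), a
# condensation (convolution) into a TCA-entry-like C4 pool, and a biomass
# drain.  12 balanced carbons, oracle-checkable.
TOY_CMP_TEXT = """\
met Aex 3 substrate
met CO2in 1 substrate
met A 3 balanced
met B 3 balanced
met C 2 balanced
met D 4 balanced
met CO2 1 sink
met Ace 2 sink
met Dex 4 sink
met BM 3 sink
upt: Aex (abc) -> A (abc)
emp: A (abc) <-> B (acb)
ppp: A (abc) -> C (ab) + CO2 (c)
pdh: B (abc) -> C (bc) + CO2 (a)
ana: C (ab) + CO2in (c) -> B (abc)
ova: C (ab) -> Ace (ab)
cnd: C (ab) + C (cd) -> D (abcd)
out_d: D (abcd) -> Dex (abcd)
bm_b: B (abc) -> BM (abc)
"""

NETWORK_PRESETS = {"TOY1": TOY1_TEXT, "TOY_CMP": TOY_CMP_TEXT}


def make_network(preset: str) -> MetabolicNetwork:
    """Parse one of the named preset networks (``TOY1`` or ``TOY_CMP``)."""
    if preset not in NETWORK_PRESETS:
        raise KeyError(f"unknown network preset {preset!r}")
    return parse_network(NETWORK_PRESETS[preset])


def _toy1_fragments() -> dict[str, FragmentDef]:
    return {
        "frag_B": FragmentDef("frag_B", "synthetic", (("B", (1, 2)),)),
        "frag_C": FragmentDef("frag_C", "synthetic", (("C", (1,)),)),
        "frag_D": FragmentDef("frag_D", "synthetic", (("D", (1,)),)),
    }


def _toy_cmp_fragments() -> dict[str, FragmentDef]:
    return {
        "frag_A": FragmentDef("frag_A", "synthetic", (("A", (1, 2, 3)),)),
        "frag_B": FragmentDef("frag_B", "synthetic", (("B", (1, 2, 3)),)),
        "frag_B23": FragmentDef("frag_B23", "synthetic", (("B", (2, 3)),)),
        "frag_C": FragmentDef("frag_C", "synthetic", (("C", (1, 2)),)),
        "frag_D": FragmentDef("frag_D", "synthetic", (("D", (1, 2, 3, 4)),)),
    }


@dataclass
class SyntheticScenario:
    """Complete specification of one synthetic study."""

    preset: str = "TOY_CMP"
    true_fluxes: FluxVector | None = None
    labeling: InputLabeling | None = None
    fragments: dict[str, FragmentDef] = field(default_factory=dict)
    mid_sd: float = 0.003  # mass-fraction units, per channel
    # culture parameters (glucose minimal-medium batch defaults)
    mu: float = 0.46  # 1/h
    nu_glucose: float = 5.9  # mmol g-DCW^-1 h^-1, uptake
    rho_acetate: float = 2.7  # mmol g-DCW^-1 h^-1, production
    rho_succinate: float = 0.2
    x0: float = 0.02  # g-DCW l^-1 at t=0
    glucose0: float = 55.5  # mmol l^-1 (10 g/l)
    t_end: float = 6.0  # h
    dt: float = 0.25  # h (15-min sampling)
    tc_noise: float = 0.0  # multiplicative SD on concentrations/biomass
    # expression parameters
    n_genes: int = 2000
    set_sizes: dict[str, int] = field(default_factory=lambda: {
        "abrb": 100, "cmp": 80, "amino": 80, "purine": 40, "pyrimidine": 30})
    n_dual: int = 10  # genes placed in both 'cmp' and 'abrb'
    set_shifts: dict[str, float] = field(default_factory=lambda: {
        "abrb": -1.0, "cmp": 0.5, "amino": 0.4, "purine": 0.4,
        "pyrimidine": 0.4})
    expr_sd: float = 0.3  # replicate noise, log2 scale
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mid_sd, self.tc_noise, self.expr_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def analyte_map(self) -> dict[str, str]:
        if self.preset == "TOY_CMP":
            return {"glucose": "upt", "acetate": "ova"}
        return {"glucose": "upt"}


def make_scenario(preset: str = "TOY_CMP", **overrides) -> SyntheticScenario:
    """Scenario with the preset's ground truth filled in."""
    if preset == "TOY1":
        truth = FluxVector({"upt": 10.0, "v1": 6.0, "v3": 4.0, "v2": 10.0,
                            "out_c": 10.0, "out_d": 10.0})
        labeling = InputLabeling({"Aex": [("10", 1.0)]})
        fragments = _toy1_fragments()
    elif preset == "TOY_CMP":
        # steady state: A: 5.9 = emp + ppp; B: emp + ana = pdh + bm;
        # C: ppp + pdh = ova + 2*cnd + ana; D: cnd = out_d.
        # Biomass drain 2.0 mmol/g-DCW * mu.
        bm = 2.0 * 0.46
        ana = 0.4
        pdh = 4.4 + ana - bm
        cnd = (1.5 + pdh - 2.7 - ana) / 2.0
        truth = FluxVector(
            {"upt": 5.9, "emp": 4.4, "ppp": 1.5, "pdh": pdh, "ana": ana,
             "ova": 2.7, "cnd": cnd, "out_d": cnd, "bm_b": bm},
            {"emp": 0.5})
        # 1,2-13C tracer mixed with unlabeled substrate: breaks positional
        # symmetry so the branch split and the exchange flux are observable
        labeling = InputLabeling({"Aex": [("110", 0.5), ("000", 0.5)],
                                  "CO2in": [("0", 1.0)]})
        fragments = _toy_cmp_fragments()
    else:
        raise KeyError(f"unknown network preset {preset!r}")
    sc = SyntheticScenario(preset=preset, true_fluxes=truth,
                           labeling=labeling, fragments=fragments)
    return replace(sc, **overrides) if overrides else sc


def precursor_demand(preset: str) -> PrecursorDemand:
    """Demand coefficients matching the preset's ground truth."""
    if preset == "TOY_CMP":
        return PrecursorDemand({"B": 2.0})
    return PrecursorDemand({})


def simulate_measurements(
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> tuple[list[MeasuredMID], TimeCourse]:
    """Noisy fragment MIDs plus a culture time course.

    MIDs: EMU-simulated truth + i.i.d. N(0, mid_sd) per channel, clipped at
    zero and renormalized.  Time course: exponential biomass with
    rate-proportional glucose consumption and acetate/succinate production,
    with multiplicative noise ``tc_noise``.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    net = make_network(scenario.preset)
    scenario.true_fluxes.validate(net)

    targets: list[EMU] = []
    for frag in scenario.fragments.values():
        targets.extend(map_fragment_to_emus(frag, net))
    emunet = decompose(net, targets)
    emu_mids = simulate_mids(emunet, scenario.true_fluxes, scenario.labeling)

    sd_report = max(scenario.mid_sd, 1e-6)
    mids: list[MeasuredMID] = []
    for fid in sorted(scenario.fragments):
        mid = predict_fragment_mid(scenario.fragments[fid], emu_mids)
        noisy = mid + rng.normal(0.0, scenario.mid_sd, size=len(mid))
        noisy = np.clip(noisy, 0.0, None)
        noisy = noisy / noisy.sum()
        mids.append(MeasuredMID(fid, noisy, np.full(len(mid), sd_report)))

    t = np.arange(0.0, scenario.t_end + 1e-9, scenario.dt)
    growth = scenario.x0 * (np.exp(scenario.mu * t) - 1.0) / scenario.mu
    x = scenario.x0 * np.exp(scenario.mu * t)
    conc = {
        "glucose": scenario.glucose0 - scenario.nu_glucose * growth,
        "acetate": scenario.rho_acetate * growth,
        "succinate": scenario.rho_succinate * growth,
    }
    if scenario.tc_noise > 0:
        x = x * (1.0 + rng.normal(0, scenario.tc_noise, size=len(t)))
        conc = {k: v * (1.0 + rng.normal(0, scenario.tc_noise, size=len(t)))
                for k, v in conc.items()}
    if np.any(conc["glucose"] < 0):
        raise ValueError("scenario depletes glucose within the time course")
    tc = TimeCourse(t, np.clip(x, 0.0, None), conc)
    return mids, tc


def simulate_expression(
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> ExpressionTable:
    """Two-condition log-normal expression table with set-level log2 shifts.

    Condition ``a`` is the baseline; genes of each configured set receive
    their set's log2 shift in condition ``b``.  ``n_dual`` genes belong to
    both the 'cmp' and 'abrb' sets (and receive the 'abrb' shift), so the
    exclusion rule has work to do.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    n = scenario.n_genes
    genes = [f"g{i:04d}" for i in range(n)]
    gene_sets: dict[str, set[str]] = {}
    cursor = 0
    for set_id, size in scenario.set_sizes.items():
        if cursor + size > n:
            raise ValueError("gene sets exceed the number of genes")
        gene_sets[set_id] = set(genes[cursor: cursor + size])
        cursor += size
    dual = set(genes[cursor: cursor + scenario.n_dual])
    gene_sets.setdefault("cmp", set()).update(dual)
    gene_sets.setdefault("abrb", set()).update(dual)
    cursor += scenario.n_dual

    base = rng.normal(8.0, 1.5, size=n)  # log2 baseline, mean signal ~500
    shift = np.zeros(n)
    for set_id, s in scenario.set_shifts.items():
        members = gene_sets.get(set_id, set())
        for i, g in enumerate(genes):
            if g in members and g not in dual:
                shift[i] += s
    for i, g in enumerate(genes):
        if g in dual:
            shift[i] = scenario.set_shifts.get("abrb", 0.0)

    cols = {}
    for r in range(scenario.n_replicates):
        cols[f"a_{r + 1}"] = 2.0 ** (base + rng.normal(0, scenario.expr_sd, n))
    for r in range(scenario.n_replicates):
        cols[f"b_{r + 1}"] = 2.0 ** (base + shift
                                     + rng.normal(0, scenario.expr_sd, n))
    signals = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    conditions = {c: c.split("_")[0] for c in signals.columns}
    return ExpressionTable(signals, conditions, gene_sets)
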
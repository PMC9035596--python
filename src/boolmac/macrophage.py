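"""The built-in macrophage differentiation model and the full-analysis driver.

The model bundles a 29-node Boolean regulatory network of macrophage
polarization (cytokine inputs ``*_e``, receptors, STAT/SOCS signaling,
NF-κB/PPARγ/HIF1α transcription factors, cytokine outputs ``*_out``), the
marker rules that map attractors onto the M0 / M1 / M2a-d / M2 / il6 cell
types, and the six polarizing micro-environments plus the free environment.

The shipped rule set is a **synthetic reconstruction**: the original model's
complete truth tables live in its supplementary material, so the rules here
were rebuilt from the constraints the article text states (node inventory,
the IL6R/STAT3/SOCS3 negative circuit, SOCS1 inhibition of STAT1/STAT5/STAT6,
environment compositions, marker semantics, mutant phenotypes).  The methods
note documents rule-by-rule provenance and which published observations the
reconstruction reproduces.  Published headline numbers (attractor counts,
transition percentages) are properties of the original truth tables and are
not built into this fixture.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import attractors as attr_mod
from . import perturb as pert_mod
from .bnet import parse_bnet
from .environments import Environment
from .labeling import (LabelRule, aggregate_basins, label_set,
                       rules_from_table)
from .network import BooleanNetwork

# sha256 of the shipped fixture files; checked at load so silent corruption
# of the model definition cannot go unnoticed.
_CHECKSUMS = {
    "macrophage_reconstruction.bnet":
        "b47b5206373f1b1d83a42aefb3b29a753daa9f24b0597cb054cc436635f9cbae",
    "macrophage_labels.csv":
        "87ca4864b13d0038da051db41ac608d99322f043828ec34fe6777a8020eef247",
    "macrophage_environments.csv":
        "d0b206dec9c175bec7d8b3eb3ec11722959a4a396fcf2f67cd84b1a232a7824c",
}

DISPLAY_ALIASES = {"STAT3_s": "STAT3*"}

#: mutants discussed against experimental data: STAT1 and PPARγ loss of
#: function, STAT6 gain of function, and the NF-κB knock-out (whose
#: experimental discordance is a known limitation of single-node NF-κB
#: models -- it is reported, not corrected).
REFERENCE_MUTANTS = [
    pert_mod.MutationSpec("STAT1", pert_mod.KNOCKOUT),
    pert_mod.MutationSpec("PPARG", pert_mod.KNOCKOUT),
    pert_mod.MutationSpec("STAT6", pert_mod.OVEREXPRESSION),
    pert_mod.MutationSpec("NFKB", pert_mod.KNOCKOUT),
]


def _load_data(name: str) -> str:
    data = resources.files("boolmac.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} is corrupt: sha256 {digest} != {_CHECKSUMS[name]}"
        )
    return data.decode("utf-8")


def load_macrophage_network() -> BooleanNetwork:
    """The 29-node macrophage network (reconstruction; see module docstring).

    Invariants checked here: 29 nodes, 52 interactions between distinct
    nodes, and the input set = the nine ``*_e`` cytokine nodes.
    """
    net = parse_bnet(
        _load_data("macrophage_reconstruction.bnet"),
        {"model": "macrophage_reconstruction",
         "aliases": dict(DISPLAY_ALIASES)},
    )
    if net.n != 29:
        raise RuntimeError(f"expected 29 nodes, fixture has {net.n}")
    inputs = net.input_nodes()
    if set(inputs) != {v for v in net.nodes if v.endswith("_e")}:
        raise RuntimeError("input set does not match the *_e nodes")
    n_inter = sum(1 for e in net.interaction_graph() if e.source != e.target)
    if n_inter != 52:
        raise RuntimeError(f"expected 52 interactions, fixture has {n_inter}")
    return net


def macrophage_label_rules() -> list[LabelRule]:
    """Marker rules for the eight base cell types, most specific first.

    Priority M2d > M2b > M2a > M2c > M2 > M1 > il6 > M0 so subtype rules fire
    before the generic M2 rule; an oscillating marker satisfies
    require-active.  M0 is the empty fallback rule.
    """
    df = pd.read_csv(_string_io(_load_data("macrophage_labels.csv")))
    return rules_from_table(df)


def macrophage_environments() -> list[Environment]:
    """The six polarizing micro-environments plus ``free``.

    Each named environment fixes every ``*_e`` input: listed cytokines to 1,
    all others to 0.  ``free`` fixes nothing.
    """
    net = load_macrophage_network()
    inputs = net.input_nodes()
    df = pd.read_csv(_string_io(_load_data("macrophage_environments.csv")))
    envs = []
    for _, row in df.iterrows():
        present = str(row["present"]).split() if pd.notna(row["present"]) else []
        unknown = set(present) - set(inputs)
        if unknown:
            raise RuntimeError(f"environment {row['name']}: unknown inputs {unknown}")
        if not present and row["name"] == "free":
            envs.append(Environment("free", {}))
        else:
            envs.append(Environment(
                str(row["name"]), {i: int(i in present) for i in inputs}))
    return envs


def _string_io(text: str):
    import io
    return io.StringIO(text)


def named_environments() -> list[Environment]:
    """The six named (fully fixed) environments, without ``free``."""
    return [e for e in macrophage_environments() if not e.free]


# ---------------------------------------------------------------------------
# one-command driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "full_census": True,           # census over every input combination
    "environments": "named",       # per-environment tables for these envs
    "single_perturbations": True,  # over named envs (records kept)
    "double_perturbations": True,  # over all combinations (summary only)
    "all_combination_stats": True,
    "mutants": True,
    "derrida_samples": 5000,
    "derrida_max_h": None,         # None = n
    "seed": 0,
}


def run_full_analysis(output_dir, config: dict | None = None,
                      network: BooleanNetwork | None = None,
                      rules: list[LabelRule] | None = None,
                      environments: list[Environment] | None = None,
                      mutants: list | None = None) -> dict:
    """Run the whole pipeline and write CSV/JSON reports.

    By default analyses the built-in macrophage model: full attractor census
    with labels, per-environment censuses, the reference mutant report,
    single (named environments, with records) and double (all input
    combinations, summary) transient perturbations, per-node transition
    rates, and the Derrida curve.  Returns the summary dict that is also
    written to ``summary.json``.

    A custom ``network`` / ``rules`` / ``environments`` triple runs the same
    pipeline on another model (used with toy networks in the test suite).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if mutants is None:
        mutants = REFERENCE_MUTANTS if network is None else []
    net = network if network is not None else load_macrophage_network()
    rules = rules if rules is not None else macrophage_label_rules()
    if environments is None:
        environments = named_environments()
    summary: dict = {"config": {k: v for k, v in cfg.items()},
                     "n_nodes": net.n,
                     "n_interactions": sum(
                         1 for e in net.interaction_graph()
                         if e.source != e.target)}

    # full census
    if cfg["full_census"]:
        aset = attr_mod.find_attractors_exhaustive(net)
        labels = label_set(aset, rules, net)
        labels.to_csv(out / "attractors_full.csv", index=False)
        steady = int((labels["period"] == 1).sum())
        cyclic = int((labels["period"] > 1).sum())
        cyc_basin = int(labels.loc[labels["period"] > 1, "basin_size"].sum())
        base = aggregate_basins(labels)
        summary["census"] = {
            "n_steady_states": steady,
            "n_cyclic_attractors": cyclic,
            "periods": sorted(int(p) for p in labels["period"].unique()),
            "pct_cyclic_of_attractors": 100.0 * cyclic / max(len(labels), 1),
            "pct_cyclic_of_state_space":
                100.0 * cyc_basin / aset.total_states,
            "basin_fraction_by_label":
                {k: v / aset.total_states for k, v in base.items()},
        }

    # per-environment censuses
    env_rows = []
    for env in environments:
        easet = attr_mod.attractors_by_environment(net, env)
        df = label_set(easet, rules, net)
        df.insert(0, "environment_name", env.name)
        env_rows.append(df)
    if env_rows:
        env_table = pd.concat(env_rows, ignore_index=True)
        env_table.to_csv(out / "attractors_by_environment.csv", index=False)
        summary["environments"] = {
            env.name: {
                lab: round(bs, 6) for lab, bs in
                (env_table[env_table.environment_name == env.name]
                 .groupby("label")["basin_size"].sum()
                 / env_table[env_table.environment_name == env.name]
                 ["basin_size"].sum()).items()
            } for env in environments
        }

    # mutants
    if cfg["mutants"]:
        rep = pert_mod.mutant_report(net, mutants, rules, environments)
        rep.to_csv(out / "mutant_report.csv", index=False)

    # transient perturbations
    if cfg["single_perturbations"]:
        recs, summ, rates = pert_mod.transition_table(
            net, environments, rules, "single", keep_records=True)
        recs.to_csv(out / "transitions_single.csv", index=False)
        rates.to_csv(out / "node_rates_named.csv", index=False)
        summary["single_named_environments"] = summ.as_dict()
    if cfg["all_combination_stats"]:
        combos = pert_mod.all_input_environments(net)
        _, summ, rates = pert_mod.transition_table(
            net, combos, rules, "single", keep_records=False)
        rates.to_csv(out / "node_rates.csv", index=False)
        summary["single_all_combinations"] = summ.as_dict()
        if cfg["double_perturbations"]:
            _, summ2, _ = pert_mod.transition_table(
                net, combos, rules, "double", keep_records=False)
            summary["double_all_combinations"] = summ2.as_dict()
    elif cfg["double_perturbations"]:
        _, summ2, _ = pert_mod.transition_table(
            net, environments, rules, "double", keep_records=False)
        summary["double_named_environments"] = summ2.as_dict()

    # Derrida curve
    points = pert_mod.derrida_map(
        net, max_h=cfg["derrida_max_h"] or net.n,
        samples=cfg["derrida_samples"], seed=cfg["seed"])
    pert_mod.derrida_table(points).to_csv(out / "derrida.csv", index=False)
    summary["derrida"] = {
        "mean_final_hamming_h1": points[0].mean_final_hamming,
        "mean_final_hamming_max":
            max(p.mean_final_hamming for p in points),
    }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
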
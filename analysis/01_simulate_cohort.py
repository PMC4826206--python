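#!/usr/bin/env python
"""Generate the synthetic study cohort all later stages analyze.

Emulates a two-view cancer cohort: mRNA and miRNA expression with two
planted molecular subtypes (mean-shift signal in a minority of features),
overall survival with a hazard ratio of 3 between subtypes and 20%
independent censoring, a scale-free-like gene interaction network with one
planted connected module per subtype, and per-subtype binary copy-number
alteration matrices (40% recurrence inside planted modules, 2% background).

Writes the cohort in the pipeline's plain TSV/SIF formats plus the ground
truth as JSON under results/data/.
"""

import json
import sys
from pathlib import Path

import fusemod as fm
from fusemod import io as fio
from fusemod.config import PipelineConfig, stage_seed

OUT = Path("results/data")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(rng_seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)

    spec = fm.CohortSpec(seed=stage_seed(cfg.rng_seed, "simulate"))
    views, truth = fm.simulate_cohort(spec)
    clinical = fm.simulate_survival(
        truth.true_labels, hazards={1: 1.0, 2: 3.0}, censor_rate=0.2,
        seed=stage_seed(cfg.rng_seed, "survival"),
    )
    net, alterations, truth = fm.simulate_network_alterations(
        truth, seed=stage_seed(cfg.rng_seed, "network")
    )

    fio.write_feature_matrix(views[0], OUT / "mrna.tsv", label="gene")
    fio.write_feature_matrix(views[1], OUT / "mirna.tsv", label="mirna")
    fio.write_clinical(clinical, OUT / "clinical.tsv")
    fio.write_network_sif(net, OUT / "network.sif")
    for k, mat in alterations.items():
        mat.to_csv(OUT / f"alterations_subtype{k}.tsv", sep="\t", index_label="gene")
    truth_json = {
        "true_labels": truth.true_labels.to_dict(),
        "planted_modules": {
            str(k): [sorted(m) for m in mods] for k, mods in truth.planted_modules.items()
        },
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))

    n_events = int(clinical["os_event"].sum())
    print(f"cohort: {spec.n_patients} patients, views {[v.shape for v in views]}")
    print(f"survival: {n_events}/{len(clinical)} deaths observed "
          f"({1 - n_events / len(clinical):.0%} censored)")
    print(f"network: {net.number_of_nodes()} genes, {net.number_of_edges()} edges; "
          f"planted modules: { {int(k): [len(m) for m in v] for k, v in truth.planted_modules.items()} }")
    print(f"wrote inputs to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
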
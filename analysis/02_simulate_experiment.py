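#!/usr/bin/env python
"""Generate a synthetic MA experiment for three bias-contrasted strains.

Simulates mutation-accumulation datasets for a transition-biased strain
("ts_strain", 95% transitions), a wild-type-like strain ("wt_like", 46%
transversions), and a transversion-biased strain ("tv_strain", 90%
transversions).  Per-line variant tables (with read support, frequencies,
and planted filter-failing decoys) are written in the pipeline's TSV
dialect together with a truth ledger.
"""

import json
from pathlib import Path

from mabias.io import write_mutation_table
from mabias.simulate import MASimConfig, SpectrumProbs, simulate_ma

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

#: mean ~1.2 mutations per line over 27 generations, so that roughly a third
#: of 300 lines carry exactly one mutation, mirroring a short MA design
MU = 1.2 / (27 * MASimConfig().genome_size)

STRAIN_CONFIGS = {
    "ts_strain": SpectrumProbs(p_tv_given_bps=0.05),
    "wt_like": SpectrumProbs(p_tv_given_bps=0.46),
    "tv_strain": SpectrumProbs(p_tv_given_bps=0.90),
}

BACKGROUND = ((2845011, "G", "A"),)  # ancestral marker present in every line


def main(seed: int = 20_240_901) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for i, (strain, probs) in enumerate(STRAIN_CONFIGS.items()):
        config = MASimConfig(
            strain_id=strain, mu=MU, n_lines=300, generations_per_line=27,
            spectrum=probs, background_mutations=BACKGROUND,
            decoy_fraction=0.15, seed=seed + i,
        )
        sim = simulate_ma(config)
        strain_dir = OUT / strain
        strain_dir.mkdir(exist_ok=True)
        write_mutation_table(sim["ancestor"], strain_dir / "ancestor.tsv")
        for line_id, table in sim["lines"].items():
            write_mutation_table(table, strain_dir / f"{line_id}.tsv")
        truth = sim["truth"]
        truth["mutations"].to_csv(strain_dir / "truth_mutations.tsv", sep="\t", index=False)
        ledger = {k: v for k, v in truth.items() if k != "mutations"}
        (strain_dir / "truth.json").write_text(json.dumps(ledger, indent=1))
        n_single = sum(1 for c in truth["per_line_counts"] if c == 1)
        summary[strain] = {
            "lines": config.n_lines,
            "true_mutations": truth["n_true_mutations"],
            "decoys": truth["n_decoys"],
            "single_mutation_lines": n_single,
        }
        print(
            f"{strain}: {config.n_lines} lines, {truth['n_true_mutations']} true mutations "
            f"({n_single} single-mutation lines), {truth['n_decoys']} filter-failing decoys"
        )
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"\nDataset written under {OUT}")


if __name__ == "__main__":
    main()
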
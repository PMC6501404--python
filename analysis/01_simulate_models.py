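#!/usr/bin/env python
"""Generate the synthetic study inputs: the core toy model (with its RPKM
condition profiles) and a panel of random models with planted essential
genes.  Everything lands under results/models/."""

from pathlib import Path

from seraflux import io, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "models"


def main() -> None:
    core = synthetic.make_toy_core_model()
    core_dir = OUT / "toy_core"
    io.write_model_dir(core, core_dir)
    synthetic.make_core_expression_profiles(seed=0).to_tsv(core_dir / "rpkm.tsv")
    print(f"toy core: {len(core.reactions)} reactions, {len(core.genes)} genes")
    print(f"  analytic optimum Z* = {core.annotations['optimum']:.4f} "
          f"(TCA silenced: {core.annotations['optimum_no_tca']:.4f})")
    print(f"  planted essentials: {core.annotations['essential_genes']}")

    for seed in range(5):
        spec = synthetic.SyntheticSpec(seed=seed, n_reactions=14)
        model = synthetic.make_random_model(spec)
        io.write_model_dir(model, OUT / f"random_{seed}")
        print(f"random_{seed}: {len(model.reactions)} reactions, "
              f"essentials {model.annotations['essential_genes']}")
    print(f"\nwrote model directories under {OUT}")


if __name__ == "__main__":
    main()
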
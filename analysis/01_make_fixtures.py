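"""Generate the synthetic fixture battery: toy structures + predictor files.

Writes, under results/fixtures/: one PDB and ground-truth pKa table per
named scenario, and a nine-predictor ΔΔG file with planted true values.
"""

from pathlib import Path

from phfold.structures import VariantSpec
from phfold.synthetic import (
    generate_predictor_file,
    generate_toy_protein,
    scenario_neutral_optimum,
    scenario_positive_regulator,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for factory in (scenario_positive_regulator, scenario_neutral_optimum):
        spec = factory(SEED)
        pdb, truth = generate_toy_protein(spec, OUT)
        print(f"{spec.name}: {sum(spec.site_counts.values())} planted sites "
              f"-> {pdb.name}, {truth.name}")

    variants = [(VariantSpec.parse("D2A"), -1.0), (VariantSpec.parse("A1E"), 0.4)]
    df = generate_predictor_file(variants, seed=SEED, noise_sd=0.5,
                                 path=OUT / "predictors.tsv")
    print(f"predictors.tsv: {len(df)} rows "
          f"({df.variant.nunique()} variants x 9 predictors)")


if __name__ == "__main__":
    main()
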
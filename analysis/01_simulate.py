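"""Generate the synthetic ASD/TD multi-omics cohort.

Writes the full bundle (clinical, variants, carriers, trios, genus counts,
metabolite intensities, ground truth) under results/simulate/ and reports
the cohort structure.
"""

import argparse

from gutbrain.pipeline import stage_simulate
from gutbrain.synthetic import SyntheticConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/simulate")
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    bundle = stage_simulate(cfg, args.outdir)
    clin = bundle.clinical
    cases = clin[clin["group"] == "ASD"]
    print(f"cohort: {len(cases)} ASD / {(clin['group'] == 'TD').sum()} TD")
    print(f"constipation in ASD: {cases['constipation'].sum()} "
          f"({100 * cases['constipation'].mean():.1f}%)")
    print(f"diarrhea in ASD: {cases['diarrhea'].sum()} "
          f"({100 * cases['diarrhea'].mean():.1f}%)")
    print(f"planted qualifying variants: "
          f"{len(bundle.truth['variants']['qualifying_variants'])}")
    print(f"wrote bundle to {args.outdir}")


if __name__ == "__main__":
    main()
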
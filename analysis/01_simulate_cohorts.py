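#!/usr/bin/env python
"""Generate the synthetic training and validation cohorts.

Writes a 200-sample training cohort, a same-platform validation cohort, and
a batch-shifted copy of the validation cohort standing in for a second
expression platform.  Expression and annotation go to TSV, the latent
carrier truth to a JSON side-car, under results/cohorts/.
"""

import argparse
import dataclasses
import json
import os

import egfr_msig as em


def write_cohort(cohort, prefix):
    em.write_expression(cohort.expression, f"{prefix}.expression.tsv")
    em.write_annotation(cohort.annotation, f"{prefix}.annotation.tsv")
    with open(f"{prefix}.truth.json", "w") as handle:
        json.dump(
            {
                "carriers": cohort.truth,
                "planted_up": cohort.planted_up,
                "planted_down": cohort.planted_down,
            },
            handle,
            indent=1,
        )


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", default="results/cohorts")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    sim = em.SimulationConfig(seed=args.seed)
    train = em.simulate_cohort(sim)
    validation = em.simulate_cohort(dataclasses.replace(sim, seed=args.seed + 500))
    shifted = em.apply_platform_shift(validation, shift_sd=0.5, seed=args.seed + 1)

    write_cohort(train, os.path.join(args.outdir, "training"))
    write_cohort(validation, os.path.join(args.outdir, "validation"))
    write_cohort(shifted, os.path.join(args.outdir, "validation_platformB"))

    for name, cohort in (("training", train), ("validation", validation)):
        n_mt = sum(a.egfr_mutant for a in cohort.annotation)
        n_carrier = sum(cohort.truth.values())
        print(
            f"{name}: {cohort.expression.n_samples} samples, "
            f"{n_mt} EGFR-mt, {n_carrier} signature carriers"
        )
    print(f"wrote cohorts to {args.outdir}/")


if __name__ == "__main__":
    main()
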
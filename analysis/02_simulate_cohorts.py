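"""Generate the two synthetic study cohorts.

Writes a drug-crossover cohort (n = 19, placebo/drug sessions, blockade shift
+0.42 on drug) and a longitudinal patient cohort (n = 42 baseline, 30
follow-ups, MMSE-linked blockade, -0.125 blockade shift and weakened deviance
modulation at follow-up) as plain-text ERP files with covariates and ground
truth.
"""
import argparse
from pathlib import Path

from nmda_dcm.cohorts import CohortSpec, generate, write_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-crossover", type=int, default=19)
    parser.add_argument("--n-longitudinal", type=int, default=42)
    args = parser.parse_args()

    for name, spec in (
        ("crossover", CohortSpec(kind="crossover", n_subjects=args.n_crossover,
                                 seed=args.seed)),
        ("longitudinal", CohortSpec(kind="longitudinal",
                                    n_subjects=args.n_longitudinal,
                                    seed=args.seed)),
    ):
        cohort = generate(spec)
        out = write_cohort(cohort, args.out / name)
        n_fup = sum(d.session == "followup" for d in cohort.datasets)
        print(f"{name}: {len(cohort.datasets)} recordings "
              f"({n_fup} follow-ups) -> {out}")


if __name__ == "__main__":
    main()
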
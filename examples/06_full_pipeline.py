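"""One-call pipeline: simulate a demo herd and run every stage to files.

Equivalent to `ch4herd run` with the default demo configuration, scaled
down so it finishes in seconds.
"""

import logging

from ch4herd import pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

out = pipeline.run_pipeline(
    {
        "outdir": "scratch/example_run",
        "seed": 7,
        "traits": ["ppm"],
        "simulate": {
            "n_founders": 40, "n_generations": 2, "matings_per_generation": 40,
            "offspring_per_mating": 2, "n_snps": 800, "n_chromosomes": 5,
            "n_days_per_cow": 15, "mean_visits_per_day": 2.0,
        },
        "reml_max_iter": 200, "reml_ltol": 1e-4,
    }
)
print(f"\nrun directory: {out}")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
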
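"""Generate the synthetic study cohort used by the downstream analyses.

500 ewe lambs (50 sires x 10 progeny, 20% link sires) across five cohorts
and three flocks, with feeder events, twice-weekly liveweights, two
accumulation-chamber rounds and CT stacks. True parameters are seeded from
the published reference estimates, so later stages can be checked by
parameter recovery. The raw tables are bulky working data, so they go
under scratch/cohort/data/; the downstream drivers write their summary
tables under results/.
"""

from rumigen.simulate import SimulationConfig, simulate_cohort

OUT = "scratch/cohort/data"


def main() -> None:
    cfg = SimulationConfig(seed=20240917, n_sires=50)
    cohort = simulate_cohort(cfg)
    cohort.write(OUT)
    print(f"simulated {len(cohort.animals)} phenotyped animals "
          f"({len(cohort.pedigree)} pedigree records) -> {OUT}")
    print(f"feeder events: {len(cohort.feeder_events):,}; "
          f"PAC readings: {len(cohort.pac):,}; "
          f"CT slice rows: {len(cohort.ct_stacks):,}")


if __name__ == "__main__":
    main()
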
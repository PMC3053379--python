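"""Find dispersed and large repeats; predict subgenomic circles.

Plants a 2.4 kb direct repeat pair plus small dispersed repeats in a 100 kb
circular genome, detects them, and derives the two subgenomic circles that
homologous recombination across the direct pair would excise from the
master circle.
"""

from mitocompare import (
    enumerate_subcircles,
    find_dispersed_repeats,
    find_large_repeats,
    repeat_coverage,
)
from mitocompare.simulate import PlantedRepeat, SimulationConfig, simulate_ancestor

config = SimulationConfig(
    seed=7,
    ancestor_length_bp=100_000,
    n_blocks=1,
    planted_repeats=[
        PlantedRepeat(2427, "direct", 1.0, positions=(10_000, 50_000)),
        PlantedRepeat(146, "inverted", 1.0, positions=(70_000, 80_000)),
        PlantedRepeat(233, "direct", 0.95, positions=(85_000, 92_000)),
    ],
)
genome = simulate_ancestor(config)

dispersed = find_dispersed_repeats(genome)
print(f"dispersed repeats (30-500 bp, >=90% identity): {len(dispersed)} pairs")
for p in dispersed:
    print(f"  {p.orientation:8s} {p.length_bp:4d} bp at "
          f"{p.interval_a.start}/{p.interval_b.start}, identity {p.identity:.3f}")
print(f"genome fraction in dispersed repeats: {repeat_coverage(genome, dispersed):.2%}")

large = find_large_repeats(genome)
pair = max((p for p in large if p.orientation == "direct"), key=lambda p: p.length_bp)
print(f"large repeat: {pair.length_bp} bp direct pair, copies at "
      f"{pair.interval_a.start} and {pair.interval_b.start}")

c1, c2 = enumerate_subcircles(genome.length_bp, pair)
print(f"subgenomic circles: {c1.length_bp} bp + {c2.length_bp} bp "
      f"(sum {c1.length_bp + c2.length_bp} = master length)")
# Recombination between the two direct copies splits the master circle into
# two circles, each keeping one repeat copy; their lengths always sum to L.
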
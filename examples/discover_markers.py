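"""Discover candidate polymorphic SSR markers between two assemblies.

Generates a synthetic assembly pair (50 planted loci, 40% with a repeat
count difference, ~1% flank SNPs in the second assembly), runs the full
conservativeness + uniqueness pipeline, and scores the result against the
generator's truth table.
"""

from ssrmine import FixtureSpec, generate_pair
from ssrmine.polymorphism_pipeline import discover_polymorphic
from ssrmine.synthetic_fixtures import evaluate_markers

spec = FixtureSpec(seed=7, n_ssrs=50, fraction_polymorphic=0.4,
                   flank_snp_rate=0.01)
assembly_a, assembly_b, truth = generate_pair(spec)

markers, summary = discover_polymorphic(assembly_a, assembly_b, spec.config)

print(f"Total number of SSR (assembly 1): {summary.total_ssrs_a}")
print(f"Number of candidate marker: {summary.candidate_markers}")
print(f"Candidate marker rate (%): {summary.candidate_marker_rate:.2f}")
print(f"Number of monomorphic SSR: {summary.monomorphic}")
print(f"Number of polymorphic SSR: {summary.polymorphic}")
print(f"Polymorphic rate (%): {summary.polymorphic_rate:.2f}")

ev = evaluate_markers(markers, truth)
print(f"\nsensitivity vs truth: {ev.sensitivity:.2f}  "
      f"precision: {ev.precision:.2f}")

print("\nfirst three markers:")
for m in markers[:3]:
    print(f"  {m.locus_a.motif} {m.locus_a.start}-{m.locus_a.end} "
          f"repeats {m.locus_a.repeats}->{m.locus_b.repeats} "
          f"[{m.stage}] {m.classification}")
# A marker is a locus pair whose 100-bp flanks are conserved between the
# assemblies (exact hash hit, or <=2 near-SSR mismatches and <=5% edit
# distance per side) and single-copy in each assembly. 'polymorphic' means
# the repeat counts differ, i.e. the marker would show a length difference
# on a gel.
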
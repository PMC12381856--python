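"""Find cryptic aggregation-prone regions and score stabilizing
mutations for surface hydrophobicity.

A per-residue aggregation-score profile with two planted APRs is
segmented at the 0.25 score threshold; residues that become exposed
during unfolding are intersected with the APRs, and APRs that are
natively buried but gain exposed residues are flagged cryptic — the
signature of aggregation triggered from a partially unfolded state.
A mutation string is then parsed, located on the native surface and
scored on two hydrophobicity scales.
"""

import numpy as np

import crypticfold as cf
from crypticfold.synthetic import gen_profiles_and_sequences

profile, sequence, planted, mut_string = gen_profiles_and_sequences(
    n_residues=296, planted_aprs=[(160, 185), (260, 280)], seed=3,
    n_mutations=6)

segments = cf.segment_aprs(profile, threshold=0.25)
print("APR segments (score > 0.25):")
for s in segments:
    print(f"  residues {s.start}-{s.end}  peak {s.peak_score:.2f}  "
          f"mean {s.mean_score:.2f}")

# suppose unfolding exposes part of the first APR plus scattered residues
newly_exposed = set(range(162, 180)) | {30, 95, 220}
native_rasa = np.full(296, 0.10)          # APRs buried in the native state
native_rasa[:50] = 0.40                   # an exposed N-terminal face

report = cf.overlap_exposed_aprs(newly_exposed, segments)
print(f"\n{report.n_newly_exposed_in_apr} of {report.n_newly_exposed} newly "
      f"exposed residues fall inside APRs ({report.fraction_pct:.0f} %)")

cryptic = cf.flag_cryptic_aprs(segments, newly_exposed, native_rasa)
for s in cryptic:
    print(f"cryptic APR: {s.start}-{s.end} (buried natively, exposed on "
          f"unfolding)")

muts = cf.parse_mutations(mut_string, sequence)
per, counts = cf.classify_mutation_locations(muts, native_rasa)
print(f"\nmutations: {cf.format_mutations(muts)}")
print(f"surface/buried: {counts['surface']} surface, {counts['buried']} buried")
for scale in ("kyte-doolittle", "eisenberg"):
    d = cf.surface_hydrophobicity_change(sequence, muts, native_rasa, scale)
    print(f"surface hydrophobicity change ({scale}): {d:+.1f} %")
print("(a large positive change on an already aggregation-prone surface "
      "is the stability-solubility trade-off in action)")
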
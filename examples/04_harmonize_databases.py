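"""Harmonize two generated toy databases and check against planted truth.

Generates a 20-compound database pair where the right-hand copies are
perturbed by Kekulé flips, atom reordering and charge shifts, plus unmatched
extra compounds on each side; then matches by tight and loose identifiers,
confirms with cross-references and validates with reaction EC numbers.
"""

import tempfile

from molcolor import harmonize_directories, make_database_pair

with tempfile.TemporaryDirectory() as td:
    pair = make_database_pair(
        seed=1,
        n_compounds=20,
        noise_profile={"kekule_flip", "charge_shift", "atom_reorder", "unmatched_extras"},
        out_dir=td,
    )
    report = harmonize_directories(pair.dir_left, pair.dir_right)

print(f"planted correspondences: {len(pair.planted)}")
print(f"recovered pairs:         {len(report.pairs)}")
found = {(p.left_id, p.right_id) for p in report.pairs}
planted = {(p.left_id, p.right_id) for p in pair.planted}
print(f"precision: {len(found & planted) / len(found):.2f}  "
      f"recall: {len(found & planted) / len(planted):.2f}")

print("\npair counts by mode / ID confirmation / EC status:")
print(report.counts.to_string(index=False))

# Every planted pair is recovered (precision = recall = 1): tight mode for
# pairs differing only by representation noise the method absorbs exactly,
# loose mode for the charge-shifted ones; EC statuses follow the planted
# reaction tables (ec4 implies ec3-level agreement as well).
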
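"""Window enumeration and peptide physicochemistry on the published panel.

Every 5-30 aa subsequence of a protein is a prediction unit; the number of
windows grows linearly with protein length (26 L - 429 for L >= 30). For
each panel peptide we print the average free-acid molecular weight and the
formal net charge — the cationic character that drives CPP behaviour.
"""

from cppscreen import (
    ProteinRecord,
    enumerate_windows,
    expected_window_count,
    net_charge,
    peptide_mass,
    table2_fixture,
)

protein = ProteinRecord("AKIP1-like", "A" * 210)  # the shortest screened protein
windows = enumerate_windows(protein)
print(f"a {protein.length}-aa protein yields {len(windows)} windows "
      f"(closed form: {expected_window_count(protein.length)})\n")

print(f"{'peptide':16s} {'sequence':20s} {'Mw (Da)':>9s} {'charge':>7s}")
for name, seq in table2_fixture():
    print(f"{name:16s} {seq:20s} {peptide_mass(seq):9.2f} {net_charge(seq):+7d}")
print("\nMw is the free-acid average mass; charge = (K+R) - (D+E).")
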
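"""NLS-consensus and molecular-sled motif scanning of the peptide panel.

Nuclear localization signals (consensus K-K/R-X-K/R, X a short span) and
molecular sleds (K/R runs of >= 3) mark peptides that could carry cargo to
the nucleus or slide along DNA — desirable extra functions in a CPP.
"""

from cppscreen import find_nls_consensus, find_sled_motifs, table2_fixture

for name, seq in table2_fixture():
    nls = find_nls_consensus(seq)
    sleds = find_sled_motifs(seq)
    parts = [f"NLS {m.text}@{m.start}" for m in nls]
    parts += [f"{m.kind} {m.text}@{m.start}" for m in sleds]
    print(f"{name:16s} {seq:20s} {'; '.join(parts) if parts else '-'}")
print("\n@n gives the 1-based match position inside the peptide.")
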
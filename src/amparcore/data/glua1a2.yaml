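# Default subunit convention for the GluA1/A2 di-heteromeric AMPAR core.
#
# Positions follow the canonical tetramer naming: GluA1 occupies A/C,
# GluA2 occupies B/D.  Residue numbers are mature-protein numbering
# (GluA1 labels run 4 lower than the homologous GluA2 labels, e.g. the
# Q/R site is Q582 in GluA1 and R586 in GluA2).  `offsets` shifts these
# to a model's author numbering per chain (default 0 = identical).
#
# D1/D2 lobe boundaries are an editable convention: the clamshell's upper
# lobe (D1) comprises most of segment S1 plus the C-terminal helices of
# S2, the lower lobe (D2) the remainder.  No single authoritative split
# exists; adjust the ranges below for other constructs.

positions: {A: A, B: B, C: C, D: D}
identities: {A: GluA1, B: GluA2, C: GluA1, D: GluA2}

lobes:
  GluA1:
    lbd: [[388, 502], [628, 771]]
    d1:  [[388, 491], [728, 771]]
    d2:  [[492, 502], [628, 727]]
  GluA2:
    lbd: [[392, 506], [632, 775]]
    d1:  [[392, 495], [732, 775]]
    d2:  [[496, 506], [632, 731]]

# Lobe-separation marker residues (Calpha-to-Calpha distances are
# measured between these): upper-lobe A737(GluA1)/S741(GluA2), lower-lobe
# S631(GluA1)/S635(GluA2).
landmarks:
  GluA1: {d1: 737, d2: 631}
  GluA2: {d1: 741, d2: 635}

# Channel-gate residues on helix M3 (GluA2 numbering T617/A621/T625,
# gating-hinge alanine A618), with the GluA1 homologs 4 lower.
gate_residues:
  GluA1: {T617: 613, A621: 617, T625: 621, hinge: 614, qr_site: 582}
  GluA2: {T617: 617, A621: 621, T625: 625, hinge: 618, qr_site: 586}

offsets: {}
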
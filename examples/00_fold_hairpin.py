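"""Fold a miRNA precursor and apply the hairpin stability gate.

Builds a stem-loop around a conserved mature sequence, folds it with the
built-in simplified MFE dynamic program and checks the
MFE/nt < -0.2 kcal/mol/nt criterion used for precursor evidence.
"""

from stressmir.simulate import build_hairpin
from stressmir.structure import fold_mfe, parse_dotbracket, passes_mfe_gate

mature = "UGUGUUCCCAGCUCGACCCCG"  # a conserved miR398 family mature
precursor, mature_iv, star_iv = build_hairpin(mature, loop_len=8)

s = fold_mfe(precursor)
print(f"precursor ({len(precursor)} nt): {s.sequence}")
print(f"structure:            {s.dotbracket}")
print(f"MFE: {s.mfe_kcal_mol:.2f} kcal/mol  ({s.mfe_per_nt:.3f} kcal/mol/nt)")
print(f"passes < -0.2 kcal/mol/nt gate: {passes_mfe_gate(s)}")
print(f"mature at {mature_iv}, planted star at {star_iv}")

# the parser interoperates with external-folder output records
rec = parse_dotbracket(s.serialize())
print(f"re-parsed energy matches: {rec.mfe_kcal_mol == round(s.mfe_kcal_mol, 2)}")
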
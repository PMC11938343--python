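"""Stepwise acidity constants from overall protonation constants.

Loads the packaged L5 ligand (an Asp/His-alternating nonapeptide carrying
nine titratable protons) and converts its cumulative log beta(HnL) ladder
into stepwise pKa values: pKa_k = log beta(HkL) - log beta(H(k-1)L).
"""

from equispec import load_fixture, stepwise_pka

model = load_fixture("L5")
betas = sorted(
    (sp for sp in model.species), key=lambda sp: -sp.coeff("H")
)
values = [sp.log_beta for sp in betas]
pkas = stepwise_pka(values)

print("overall log beta (H9L ... HL):", values)
print("stepwise pKa (most acidic first):", [round(p, 2) for p in pkas])
print(
    "The first four steps (pKa ~2.2-4.1) are the Asp carboxylates; the last"
    "\nfive (pKa ~5.8-8.0) are the His imidazoles. Their sum telescopes back"
    f"\nto log beta(H9L) = {sum(pkas):.2f}."
)
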
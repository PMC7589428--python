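# Radionuclide registry: name -> physical constants.
#
# half_life_h          physical half-life in hours
# energy_per_decay_j   energy (J) deposited locally per nuclear transformation
#                      (electron/beta component); NOT bundled -- supply it from
#                      a decay-data compilation (ICRP 107, MIRD) either here in
#                      a user copy of this file or via load_nuclide(...,
#                      energy_per_decay_j=...).
Lu-177:
  half_life_h: 159.53
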
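# Packaged degradation schedules: pressure-indexed graph-edit budgets for
# the shock-compression emulator. S = small (2-chain) particle, L = large
# (4-chain) particle; the number is the compression pressure label in GPa
# (an index into this table, no physics implied).
#
# n_OH/n_COOH/n_CHO/n_CO/n_R3..n_R6/n_Ow are the final census targets for
# the main particle; n_scission is the number of ester linkages destroyed
# (pristine ester count minus the final one); n_crosslink is the number of
# new C-C bonds fusing the cut segments into a single molecule; and
# n_detach_fragments is the number of 2-18 carbon fragments released.
S10: {size_class: S, pressure: 10, n_OH: 0, n_COOH: 0, n_CHO: 0, n_CO: 0,
      n_R3: 0, n_R4: 0, n_R5: 2, n_R6: 0,
      n_scission: 3, n_crosslink: 4, n_detach_fragments: 0, n_Ow: 0, seed: 42}
S20: {size_class: S, pressure: 20, n_OH: 25, n_COOH: 0, n_CHO: 1, n_CO: 0,
      n_R3: 0, n_R4: 7, n_R5: 9, n_R6: 0,
      n_scission: 60, n_crosslink: 57, n_detach_fragments: 2, n_Ow: 22, seed: 42}
S25: {size_class: S, pressure: 25, n_OH: 141, n_COOH: 21, n_CHO: 10, n_CO: 3,
      n_R3: 5, n_R4: 3, n_R5: 8, n_R6: 7,
      n_scission: 198, n_crosslink: 191, n_detach_fragments: 4, n_Ow: 173, seed: 42}
S30: {size_class: S, pressure: 30, n_OH: 231, n_COOH: 25, n_CHO: 11, n_CO: 14,
      n_R3: 5, n_R4: 5, n_R5: 16, n_R6: 11,
      n_scission: 269, n_crosslink: 258, n_detach_fragments: 6, n_Ow: 284, seed: 42}
L10: {size_class: L, pressure: 10, n_OH: 0, n_COOH: 0, n_CHO: 0, n_CO: 0,
      n_R3: 0, n_R4: 1, n_R5: 3, n_R6: 0,
      n_scission: 9, n_crosslink: 12, n_detach_fragments: 0, n_Ow: 0, seed: 42}
L20: {size_class: L, pressure: 20, n_OH: 85, n_COOH: 6, n_CHO: 3, n_CO: 0,
      n_R3: 0, n_R4: 9, n_R5: 13, n_R6: 6,
      n_scission: 170, n_crosslink: 167, n_detach_fragments: 3, n_Ow: 65, seed: 42}
L25: {size_class: L, pressure: 25, n_OH: 209, n_COOH: 19, n_CHO: 6, n_CO: 7,
      n_R3: 4, n_R4: 9, n_R5: 24, n_R6: 11,
      n_scission: 358, n_crosslink: 349, n_detach_fragments: 6, n_Ow: 194, seed: 42}
L30: {size_class: L, pressure: 30, n_OH: 357, n_COOH: 42, n_CHO: 19, n_CO: 18,
      n_R3: 6, n_R4: 5, n_R5: 25, n_R6: 23,
      n_scission: 504, n_crosslink: 491, n_detach_fragments: 8, n_Ow: 414, seed: 42}
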
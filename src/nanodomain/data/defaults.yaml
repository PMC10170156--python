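# Default operating point of the nanodomain lattice model.
# Lengths in um, times in s, energies in k_B*T, rates in 1/s.
D: 0.2
dx: 0.002
L: 0.2
n_tet: 10
n_cla: 10
r_dom: 0.0056
E_entry_tet: 11.5
E_exit_tet: 13.0
E_entry_cla: 1.0
E_exit_cla: 4.5
k_bind: 0.0
k_remove: 0.05
T_max: 1000.0
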
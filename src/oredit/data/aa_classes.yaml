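# Physicochemical classes of the 20 standard residues (one-letter codes).
hydrophobic: [G, A, V, L, I, M, F, W]
neutral: [P, S, T, C, Y, N, Q]
hydrophilic: [D, E, K, R, H]
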
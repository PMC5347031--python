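# Explicit-solvent MD protocol template (documentation only)

`sahelix` analyses trajectories; it does not run molecular dynamics.  For
users who want to generate trajectories comparable to the ones the
analysis defaults assume, the reference protocol is:

| Step | Setting |
| --- | --- |
| Force field | CHARMM36, TIP3P water |
| Starting structure | ideal α-helix (φ = −57°, ψ = −47°), ACE/CT3 caps |
| Vacuum minimization | 1,000 steepest-descent steps (CHARMM) |
| Solvation | 1.5 nm water surround; Na⁺/Cl⁻ to neutrality, ~150 mM NaCl (VMD) |
| Solvated minimization | 10,000 steps (NAMD) |
| Heating | 0 → 300 K |
| Pre-equilibration | 100,000 steps |
| Production | 200 ns at 300 K (NAMD) |
| Timestep | 2 fs |
| Frame output | every 500 steps → 1 ps/frame |

The 1 ps/frame output interval is the package's default `frame_interval`;
pass `--interval-ps` to `sahelix trajstats` if your protocol differs.
Convert DCD/XTC output to multi-model PDB (or adapt `sahelix.io` to your
reader) before analysis.
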
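# minibeams ion species table, version 1
# name	z	a	m_u(MeV per nucleon, nuclear rest energy / A)
proton	1	1	938.272
deuteron	1	2	937.806
he4	2	4	931.845
li7	3	7	933.405
c12	6	12	931.238
# material constants (liquid water)
# water	density(g/cm3)=1.0	radiation_length(g/cm2)=36.08	mean_excitation_energy(eV)=75.0	electrons_per_gram=3.3428e23
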
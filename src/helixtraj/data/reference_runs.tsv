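# Published unfolding properties of 28 all-atom MD runs of a 20-residue
# protonated poly-glutamic acid: unfolding time t_u (ns), region unfolding
# order (N = residues 2-7, M = 8-13, C = 14-19), and helix content P(H)+P(G).
# "Ide" runs started from an ideal built helix, "Sim" runs from a simulated
# helical conformation.
run_id	group	t_u_ns	order	helix_content
Ide1	Ide	8.52	N,C,M	0.34
Ide2	Ide	36.98	C,N,M	0.34
Ide3	Ide	88.26	C,N,M	0.64
Ide4	Ide	10.30	C,M,N	0.13
Ide5	Ide	74.82	C,M,N	0.20
Ide6	Ide	47.62	C,N,M	0.32
Ide7	Ide	18.10	C,N,M	0.15
Ide8	Ide	40.42	C,N,M	0.30
Ide9	Ide	23.88	C,N,M	0.14
Ide10	Ide	101.34	N,C,M	0.47
Ide11	Ide	257.92	C,N,M	0.60
Ide12	Ide	16.32	C,M,N	0.30
Ide13	Ide	29.52	N,C,M	0.62
Ide14	Ide	19.40	N,C,M	0.45
Ide15	Ide	249.24	C,N,M	0.60
Ide16	Ide	13.02	N,C,M	0.09
Ide17	Ide	23.62	C,N,M	0.14
Ide18	Ide	35.06	C,N,M	0.44
Ide19	Ide	192.74	N,C,M	0.50
Ide20	Ide	165.86	N,C,M	0.41
Sim1	Sim	31.06	C,N,M	0.15
Sim2	Sim	100.52	C,N,M	0.12
Sim3	Sim	7.38	C,N,M	0.08
Sim4	Sim	79.66	C,M,N	0.51
Sim5	Sim	24.38	C,M,N	0.22
Sim6	Sim	380.74	N,C,M	0.65
Sim7	Sim	87.06	C,N,M	0.35
Sim8	Sim	23.22	C,N,M	0.08
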
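# synthetic stand-in SBS signature catalog v1 (package-made test signatures, not published matrices)
channel	SYN_FLAT	SYN_CPG	SYN_UV	SYN_OXID
A[C>A]A	0.010656869440	0.001086956522	0.000909090909	0.053125000000
A[C>A]C	0.011172403724	0.001086956522	0.000909090909	0.053125000000
A[C>A]G	0.010942165994	0.001086956522	0.000909090909	0.053125000000
A[C>A]T	0.009899272137	0.001086956522	0.000909090909	0.053125000000
C[C>A]A	0.010041283822	0.001086956522	0.000909090909	0.053125000000
C[C>A]C	0.011127578650	0.001086956522	0.000909090909	0.053125000000
C[C>A]G	0.009482587305	0.001086956522	0.000909090909	0.053125000000
C[C>A]T	0.011028447713	0.001086956522	0.000909090909	0.053125000000
G[C>A]A	0.010982677966	0.001086956522	0.000909090909	0.053125000000
G[C>A]C	0.010359125324	0.001086956522	0.000909090909	0.053125000000
G[C>A]G	0.010046713792	0.001086956522	0.000909090909	0.053125000000
G[C>A]T	0.010000095630	0.001086956522	0.000909090909	0.053125000000
T[C>A]A	0.009955468214	0.001086956522	0.000909090909	0.053125000000
T[C>A]C	0.010315819105	0.001086956522	0.000909090909	0.053125000000
T[C>A]G	0.010428490053	0.001086956522	0.000909090909	0.053125000000
T[C>A]T	0.010521225207	0.001086956522	0.000909090909	0.053125000000
A[C>G]A	0.011358609672	0.001086956522	0.000909090909	0.001875000000
A[C>G]C	0.010974327840	0.001086956522	0.000909090909	0.001875000000
A[C>G]G	0.010651344563	0.001086956522	0.000909090909	0.001875000000
A[C>G]T	0.011346219234	0.001086956522	0.000909090909	0.001875000000
C[C>G]A	0.009880519222	0.001086956522	0.000909090909	0.001875000000
C[C>G]C	0.009776137357	0.001086956522	0.000909090909	0.001875000000
C[C>G]G	0.010633082077	0.001086956522	0.000909090909	0.001875000000
C[C>G]T	0.009555861187	0.001086956522	0.000909090909	0.001875000000
G[C>G]A	0.009540209156	0.001086956522	0.000909090909	0.001875000000
G[C>G]C	0.010448080478	0.001086956522	0.000909090909	0.001875000000
G[C>G]G	0.010355849832	0.001086956522	0.000909090909	0.001875000000
G[C>G]T	0.011210206971	0.001086956522	0.000909090909	0.001875000000
T[C>G]A	0.010664695310	0.001086956522	0.000909090909	0.001875000000
T[C>G]C	0.010446619473	0.001086956522	0.000909090909	0.001875000000
T[C>G]G	0.010413949928	0.001086956522	0.000909090909	0.001875000000
T[C>G]T	0.009941534635	0.001086956522	0.000909090909	0.001875000000
A[C>T]A	0.009494956114	0.001086956522	0.000909090909	0.001875000000
A[C>T]C	0.009837122242	0.001086956522	0.000909090909	0.001875000000
A[C>T]G	0.010783682432	0.224999999976	0.000909090909	0.001875000000
A[C>T]T	0.009852666003	0.001086956522	0.000909090909	0.001875000000
C[C>T]A	0.010172706891	0.001086956522	0.115000000008	0.001875000000
C[C>T]C	0.009479686673	0.001086956522	0.115000000000	0.001875000000
C[C>T]G	0.011045156096	0.225000000000	0.115000000000	0.001875000000
C[C>T]T	0.009765242048	0.001086956522	0.115000000000	0.001875000000
G[C>T]A	0.009979584948	0.001086956522	0.000909090909	0.001875000000
G[C>T]C	0.011140421065	0.001086956522	0.000909090909	0.001875000000
G[C>T]G	0.010438422183	0.225000000000	0.000909090909	0.001875000000
G[C>T]T	0.011077557197	0.001086956522	0.000909090909	0.001875000000
T[C>T]A	0.010684570579	0.001086956522	0.115000000000	0.001875000000
T[C>T]C	0.010877913753	0.001086956522	0.115000000000	0.001875000000
T[C>T]G	0.009645952542	0.225000000000	0.115000000000	0.001875000000
T[C>T]T	0.010497821166	0.001086956522	0.115000000000	0.001875000000
A[T>A]A	0.010434597950	0.001086956522	0.000909090909	0.001875000000
A[T>A]C	0.011123384047	0.001086956522	0.000909090909	0.001875000000
A[T>A]G	0.010157034925	0.001086956522	0.000909090909	0.001875000000
A[T>A]T	0.010605885191	0.001086956522	0.000909090909	0.001875000000
C[T>A]A	0.009584865632	0.001086956522	0.000909090909	0.001875000000
C[T>A]C	0.010206989203	0.001086956522	0.000909090909	0.001875000000
C[T>A]G	0.010084611666	0.001086956522	0.000909090909	0.001875000000
C[T>A]T	0.009757168821	0.001086956522	0.000909090909	0.001875000000
G[T>A]A	0.011019182903	0.001086956522	0.000909090909	0.001875000000
G[T>A]C	0.010191481345	0.001086956522	0.000909090909	0.001875000000
G[T>A]G	0.011326871872	0.001086956522	0.000909090909	0.001875000000
G[T>A]T	0.010590364554	0.001086956522	0.000909090909	0.001875000000
T[T>A]A	0.010618904702	0.001086956522	0.000909090909	0.001875000000
T[T>A]C	0.010681310890	0.001086956522	0.000909090909	0.001875000000
T[T>A]G	0.010754162216	0.001086956522	0.000909090909	0.001875000000
T[T>A]T	0.009758283350	0.001086956522	0.000909090909	0.001875000000
A[T>C]A	0.010306795800	0.001086956522	0.000909090909	0.001875000000
A[T>C]C	0.009926471363	0.001086956522	0.000909090909	0.001875000000
A[T>C]G	0.010235154115	0.001086956522	0.000909090909	0.001875000000
A[T>C]T	0.009655820141	0.001086956522	0.000909090909	0.001875000000
C[T>C]A	0.011306184003	0.001086956522	0.000909090909	0.001875000000
C[T>C]C	0.009879942036	0.001086956522	0.000909090909	0.001875000000
C[T>C]G	0.010745286225	0.001086956522	0.000909090909	0.001875000000
C[T>C]T	0.010041764646	0.001086956522	0.000909090909	0.001875000000
G[T>C]A	0.011128570585	0.001086956522	0.000909090909	0.001875000000
G[T>C]C	0.010727192732	0.001086956522	0.000909090909	0.001875000000
G[T>C]G	0.009721961181	0.001086956522	0.000909090909	0.001875000000
G[T>C]T	0.011073624310	0.001086956522	0.000909090909	0.001875000000
T[T>C]A	0.011262837558	0.001086956522	0.000909090909	0.001875000000
T[T>C]C	0.011185102683	0.001086956522	0.000909090909	0.001875000000
T[T>C]G	0.010551957763	0.001086956522	0.000909090909	0.001875000000
T[T>C]T	0.009748189211	0.001086956522	0.000909090909	0.001875000000
A[T>G]A	0.009837238473	0.001086956522	0.000909090909	0.001875000000
A[T>G]C	0.011230550185	0.001086956522	0.000909090909	0.001875000000
A[T>G]G	0.010519006978	0.001086956522	0.000909090909	0.001875000000
A[T>G]T	0.009814672823	0.001086956522	0.000909090909	0.001875000000
C[T>G]A	0.011147477669	0.001086956522	0.000909090909	0.001875000000
C[T>G]C	0.010688084043	0.001086956522	0.000909090909	0.001875000000
C[T>G]G	0.010551910640	0.001086956522	0.000909090909	0.001875000000
C[T>G]T	0.010185497807	0.001086956522	0.000909090909	0.001875000000
G[T>G]A	0.010251176061	0.001086956522	0.000909090909	0.001875000000
G[T>G]C	0.009926329749	0.001086956522	0.000909090909	0.001875000000
G[T>G]G	0.009544712450	0.001086956522	0.000909090909	0.001875000000
G[T>G]T	0.011132628239	0.001086956522	0.000909090909	0.001875000000
T[T>G]A	0.010358737447	0.001086956522	0.000909090909	0.001875000000
T[T>G]C	0.010510119227	0.001086956522	0.000909090909	0.001875000000
T[T>G]G	0.010082957679	0.001086956522	0.000909090909	0.001875000000
T[T>G]T	0.010896013968	0.001086956522	0.000909090909	0.001875000000
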
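# SYNTHETIC pairwise residue contact potential (units of kT), NOT a published table.
# Constructed as -0.6*(h_X+h_Y) + 0.6*q_X*q_Y + frozen Gaussian pair coupling (sd 0.5) - 2.0,
# where h is the standardized Miyazawa (1985) one-body contact-energy scale and q is net charge.
A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-1.742367	-2.255526	-0.997781	-1.603475	-2.847635	-1.272991	-1.681789	-2.895000	-1.544343	-2.734628	-2.772883	-1.670581	-0.585607	-0.721711	-1.712688	-1.562301	-1.092282	-2.328153	-2.297352	-1.470362
C	-2.255526	-2.873826	-2.192540	-2.123645	-3.688130	-2.268388	-2.988574	-3.942478	-1.333296	-3.205329	-3.939046	-1.645073	-2.125568	-2.402676	-2.463559	-2.230864	-1.812196	-3.527755	-3.171348	-2.988886
D	-0.997781	-2.192540	-0.673352	0.239091	-2.561349	-1.454734	-1.039960	-2.316752	-0.599722	-2.662647	-2.430966	-0.943847	-0.940047	-1.198173	-1.776255	-0.965075	-1.067502	-2.027038	-2.470457	-1.446055
E	-1.603475	-2.123645	0.239091	-0.147645	-2.425907	-1.054312	-1.608256	-1.880874	-1.606607	-2.404086	-1.773741	-0.672843	-1.158365	-0.884462	-1.380076	-0.203199	-1.096423	-1.490774	-2.131302	-1.453483
F	-2.847635	-3.688130	-2.561349	-2.425907	-4.278592	-2.767389	-2.656737	-3.389842	-2.792450	-4.369333	-4.081181	-2.696923	-2.005128	-2.798715	-2.572752	-2.175610	-2.401090	-3.929773	-3.310742	-3.195366
G	-1.272991	-2.268388	-1.454734	-1.054312	-2.767389	-0.873589	-2.230336	-2.714514	-0.844936	-2.609562	-2.818225	-1.616764	-0.952080	-0.811099	-1.302566	-1.125419	-0.826225	-1.717150	-2.711187	-1.580522
H	-1.681789	-2.988574	-1.039960	-1.608256	-2.656737	-2.230336	-1.096016	-2.812112	-0.405626	-2.399636	-2.758460	-1.607575	-1.491451	-1.756341	-0.848619	-1.488910	-0.903709	-2.427436	-2.619554	-1.787690
I	-2.895000	-3.942478	-2.316752	-1.880874	-3.389842	-2.714514	-2.812112	-3.472190	-1.484371	-3.653529	-3.960559	-2.541358	-2.259092	-2.686547	-2.520062	-2.316940	-2.277198	-3.258287	-3.860378	-3.453820
K	-1.544343	-1.333296	-0.599722	-1.606607	-2.792450	-0.844936	-0.405626	-1.484371	-0.503267	-2.558587	-1.377820	-0.666747	0.264894	-1.025113	-0.959696	-0.344014	-1.107403	-1.876928	-1.815524	-1.466060
L	-2.734628	-3.205329	-2.662647	-2.404086	-4.369333	-2.609562	-2.399636	-3.653529	-2.558587	-3.684438	-3.846075	-2.127125	-1.661261	-2.433300	-1.838703	-2.418787	-2.017595	-3.329534	-3.422266	-2.833051
M	-2.772883	-3.939046	-2.430966	-1.773741	-4.081181	-2.818225	-2.758460	-3.960559	-1.377820	-3.846075	-3.937745	-2.025440	-2.094156	-1.997188	-2.662271	-2.432774	-2.188605	-3.804115	-3.647900	-2.727481
N	-1.670581	-1.645073	-0.943847	-0.672843	-2.696923	-1.616764	-1.607575	-2.541358	-0.666747	-2.127125	-2.025440	-0.849659	-1.426483	-1.635480	-0.935646	-0.736917	-0.128043	-2.467286	-1.745966	-1.645990
P	-0.585607	-2.125568	-0.940047	-1.158365	-2.005128	-0.952080	-1.491451	-2.259092	0.264894	-1.661261	-2.094156	-1.426483	-1.273137	-1.468061	-0.593897	-1.403987	-1.179297	-1.997778	-2.194263	-1.393607
Q	-0.721711	-2.402676	-1.198173	-0.884462	-2.798715	-0.811099	-1.756341	-2.686547	-1.025113	-2.433300	-1.997188	-1.635480	-1.468061	-1.004574	-1.433427	-1.516178	-0.881068	-1.887350	-2.224440	-1.513007
R	-1.712688	-2.463559	-1.776255	-1.380076	-2.572752	-1.302566	-0.848619	-2.520062	-0.959696	-1.838703	-2.662271	-0.935646	-0.593897	-1.433427	-0.586726	-1.396361	-0.818908	-2.309502	-2.158319	-1.415176
S	-1.562301	-2.230864	-0.965075	-0.203199	-2.175610	-1.125419	-1.488910	-2.316940	-0.344014	-2.418787	-2.432774	-0.736917	-1.403987	-1.516178	-1.396361	-0.708757	-1.468745	-1.903131	-2.003730	-1.977842
T	-1.092282	-1.812196	-1.067502	-1.096423	-2.401090	-0.826225	-0.903709	-2.277198	-1.107403	-2.017595	-2.188605	-0.128043	-1.179297	-0.881068	-0.818908	-1.468745	-2.252645	-2.052212	-2.131996	-0.999295
V	-2.328153	-3.527755	-2.027038	-1.490774	-3.929773	-1.717150	-2.427436	-3.258287	-1.876928	-3.329534	-3.804115	-2.467286	-1.997778	-1.887350	-2.309502	-1.903131	-2.052212	-2.167830	-3.046259	-2.509975
W	-2.297352	-3.171348	-2.470457	-2.131302	-3.310742	-2.711187	-2.619554	-3.860378	-1.815524	-3.422266	-3.647900	-1.745966	-2.194263	-2.224440	-2.158319	-2.003730	-2.131996	-3.046259	-3.344701	-2.292828
Y	-1.470362	-2.988886	-1.446055	-1.453483	-3.195366	-1.580522	-1.787690	-3.453820	-1.466060	-2.833051	-2.727481	-1.645990	-1.393607	-1.513007	-1.415176	-1.977842	-0.999295	-2.509975	-2.292828	-1.665747
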
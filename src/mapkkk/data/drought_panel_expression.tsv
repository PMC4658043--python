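line	MAPKKK18	MAPKKK19	MAPKKK20	MAPKKK21	MAPKKK22	MAPKKK26	MAPKKK56	MAPKKK73
X178	58.4852	20.2990	14.7571	4.2086	7.3785	1.3883	11.7127	1.7777
J24	7.9815	4.9933	1.4175	1.5333	1.3272	4.4280	1.6818	7.3107
Q319	3.4983	4.3873	5.5854	1.8921	1.8404	1.4777	4.5525	3.8194
J853	23.5339	11.6318	5.3889	25.2813	32.7480	1.1783	7.6387	1.4777
C8605	4.5106	5.4768	5.1337	1.0930	0.8409	0.7287	4.2772	1.0892
B73	1.8877	3.6385	2.4172	0.4687	0.3209	0.9065	1.7053	1.2805
200B	8.8356	13.4543	7.4988	1.6021	1.0570	0.4043	1.4880	1.4948
E28	2.8219	0.0914	0.2038	2.6208	0.6402	0.8141	1.6663	0.5188
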
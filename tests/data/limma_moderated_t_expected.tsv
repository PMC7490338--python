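feature	t	p
F000	 0.6152077339649046	0.556079042163954762
F001	 1.9630866750097193	0.086485716424791220
F002	-0.8928558209827315	0.398858789604267128
F003	 0.1807875911290245	0.861180907918116301
F004	-5.2635813669655178	0.000848714550855678
F005	 0.1489436699803820	0.885407670000743718
F006	-0.8283112791322211	0.432306198602345648
F007	-3.3189306225176067	0.011073520306317452
F008	-0.0839503734525402	0.935227706186432695
F009	 1.4216668678210287	0.194163175758747086
F010	-0.8061457547923887	0.444233267867183423
F011	 0.5859039422271375	0.574632061495004676
F012	 0.2348173074653329	0.820446672172449931
F013	-1.0782676533597249	0.313387042836771545
F014	-1.2585945795612234	0.244832579866916117
F015	 1.0703428172427720	0.316722387436206843
F016	 1.7249768780674295	0.124104094433557785
F017	 0.6843839177784703	0.513710398129181511
F018	-4.8617154586813021	0.001379447801198280
F019	-1.0756414998076294	0.314489227543579331
F020	-0.1548316975050681	0.880917501473721831
F021	 0.4051221851318851	0.696359844650160653
F022	-1.2257197958403891	0.256309431681382427
F023	 0.6961044513313139	0.506735887788961614
F024	-5.1825463316491565	0.000934338197661417
F025	-2.1584628979656499	0.064091895509217900
F026	-2.4397292727142674	0.041578780442806842
F027	 0.7713638039588149	0.463400388675155428
F028	-1.2329069218370181	0.253762589513316539
F029	-1.0145202788209817	0.341012469025660847
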
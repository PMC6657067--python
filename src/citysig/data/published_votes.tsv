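sample_id	set	rf_prediction	rf_score	rf_departures	rf_adjusted	svm_prediction	svm_score	svm_departures	svm_adjusted	final	true_city	status
C1.001	mystery1	SAC	1.000	0	1.000	SAC	0.848	2	0.240	SAC	SCL	WRONG
C1.002	mystery1	SCL	1.000	0	1.000	SCL	1.000	0	1.000	SCL	SCL	CORRECT
C1.003	mystery1	NYC	1.000	0	1.000	NYC	0.771	1	0.297	NYC	OFA	WRONG
C1.004	mystery1	PXO	1.000	0	1.000	PXO	1.000	1	0.500	PXO	PXO	CORRECT
C1.005	mystery1	NYC	1.000	0	1.000	OFA	1.000	1	0.500	NYC	OFA	WRONG
C1.006	mystery1	PXO	0.999	1	0.499	PXO	0.821	3	0.168	PXO	PXO	CORRECT
C1.007	mystery1	SCL	0.971	1	0.471	SCL	0.769	1	0.296	SCL	SCL	CORRECT
C1.008	mystery1	PXO	1.000	0	1.000	PXO	0.696	3	0.121	PXO	PXO	CORRECT
C1.009	mystery1	NYC	1.000	0	1.000	OFA	0.619	1	0.192	NYC	NYC	CORRECT
C1.010	mystery1	PXO	1.000	0	1.000	PXO	0.698	2	0.162	PXO	PXO	CORRECT
C1.011	mystery1	SCL	1.000	0	1.000	SCL	0.741	4	0.110	SCL	SCL	CORRECT
C1.012	mystery1	OFA	1.000	0	1.000	OFA	1.000	0	1.000	OFA	OFA	CORRECT
C1.013	mystery1	PXO	1.000	0	1.000	PXO	0.864	2	0.249	PXO	PXO	CORRECT
C1.014	mystery1	SAC	1.000	0	1.000	SCL	0.717	2	0.171	SAC	SCL	WRONG
C1.015	mystery1	TOK	1.000	0	1.000	HAM	0.462	3	0.053	TOK	NYC	WRONG
C1.016	mystery1	OFA	0.913	1	0.416	NYC	0.826	1	0.341	OFA	NYC	WRONG
C1.017	mystery1	SCL	0.610	1	0.186	TOK	0.543	3	0.074	SCL	PXO	WRONG
C1.018	mystery1	NYC	1.000	0	1.000	NYC	0.995	1	0.495	NYC	NYC	CORRECT
C1.019	mystery1	AKL	1.000	0	1.000	OFA	1.000	0	1.000	Inconclusive	NYC	INCONCLUSIVE
C1.020	mystery1	OFA	1.000	0	1.000	OFA	1.000	1	0.500	OFA	OFA	CORRECT
C1.021	mystery1	AKL	0.834	3	0.174	OFA	0.997	3	0.248	OFA	NYC	WRONG
C1.022	mystery1	PXO	1.000	0	1.000	PXO	0.894	1	0.399	PXO	PXO	CORRECT
C1.023	mystery1	NYC	1.000	1	0.500	NYC	0.990	2	0.327	NYC	NYC	CORRECT
C1.024	mystery1	NYC	0.852	1	0.363	NYC	0.898	4	0.161	NYC	NYC	CORRECT
C1.025	mystery1	NYC	1.000	0	1.000	NYC	0.997	4	0.199	NYC	NYC	CORRECT
C1.026	mystery1	PXO	1.000	0	1.000	PXO	1.000	0	1.000	PXO	PXO	CORRECT
C1.027	mystery1	PXO	1.000	0	1.000	TOK	0.621	1	0.193	PXO	PXO	CORRECT
C1.028	mystery1	OFA	1.000	0	1.000	OFA	1.000	0	1.000	OFA	OFA	CORRECT
C1.029	mystery1	AKL	1.000	1	0.500	NYC	0.494	3	0.061	AKL	NYC	WRONG
C1.030	mystery1	TOK	0.761	1	0.290	TOK	0.994	1	0.494	TOK	PXO	WRONG
C5.001	mystery3	Boston	1.000	0	1.000	Boston	1.000	0	1.000	Boston	Boston	CORRECT
C5.002	mystery3	Ilorin	1.000	0	1.000	Lisbon	0.754	1	0.284	Ilorin	Ilorin	CORRECT
C5.003	mystery3	Lisbon	1.000	0	1.000	Lisbon	1.000	0	1.000	Lisbon	Lisbon	CORRECT
C5.004	mystery3	Ilorin	1.000	0	1.000	Ilorin	0.568	1	0.161	Ilorin	Ilorin	CORRECT
C5.005	mystery3	Lisbon	1.000	0	1.000	Lisbon	0.999	1	0.499	Lisbon	Lisbon	CORRECT
C5.006	mystery3	Lisbon	1.000	0	1.000	Ilorin	0.616	1	0.190	Lisbon	Ilorin	WRONG
C5.007	mystery3	Boston	1.000	0	1.000	Lisbon	0.749	1	0.280	Boston	Bogota	WRONG
C5.008	mystery3	Lisbon	0.999	1	0.499	Lisbon	0.772	1	0.298	Lisbon	Bogota	WRONG
C5.009	mystery3	Lisbon	1.000	0	1.000	Lisbon	1.000	0	1.000	Lisbon	Lisbon	CORRECT
C5.010	mystery3	Ilorin	0.384	2	0.049	Boston	0.982	1	0.482	Boston	Bogota	WRONG
C5.011	mystery3	Lisbon	1.000	0	1.000	Lisbon	1.000	0	1.000	Lisbon	Bogota	WRONG
C5.012	mystery3	Lisbon	1.000	0	1.000	Lisbon	0.988	1	0.488	Lisbon	Lisbon	CORRECT
C5.013	mystery3	Boston	1.000	0	1.000	Boston	0.998	1	0.498	Boston	Boston	CORRECT
C5.014	mystery3	Ilorin	1.000	0	1.000	Ilorin	1.000	0	1.000	Ilorin	Ilorin	CORRECT
C5.015	mystery3	Boston	1.000	0	1.000	Lisbon	0.750	1	0.282	Boston	Boston	CORRECT
C5.016	mystery3	Boston	0.843	1	0.356	Lisbon	0.750	1	0.282	Boston	Bogota	WRONG
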
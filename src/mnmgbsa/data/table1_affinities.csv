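pdb_id,resolution_A,dg_exp_kcal_mol
1ACB,2.0,-13.1
1ZHI,2.7,-9.1
1AVX,1.9,-12.5
2HLE,2.05,-10.1
1AY7,1.7,-13.2
2HRK,2.05,-11.0
1BVN,2.5,-15.1
2OOB,1.9,-5.7
1EMV,1.7,-18.6
2OUL,2.2,-12.0
1FLE,1.9,-12.3
2SIC,1.8,-13.8
1GLA,2.6,-6.8
2SNI,2.1,-16.0
1KAC,2.6,-10.7
2UUY,1.15,-11.3
1R0R,1.1,-14.2
3BZD,2.3,-9.6
1YVB,2.7,-11.2
3SGB,1.8,-14.5
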
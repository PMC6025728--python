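{
 "dependency_matrix.tsv": "260d4dbc5af0446e354a885c21047e21db188dc7b62d8535653a044af633f9bc",
 "table1.tsv": "7452eb3a2351323e32a5996c0f5c319cd38dec5ac00779bff915a4b19afa3872",
 "table2.tsv": "c7921c0646db3edeba479323db76d82afe8720811c669e70b06abdabc1eeaf3b",
 "table3.tsv": "f60dd51ff3077b076b2595ddcc3bdc88f152d97027b70456ce75ff9c639f652e"
}
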
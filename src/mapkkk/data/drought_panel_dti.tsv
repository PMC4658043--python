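line	fresh	dry
X178	0.739	0.812
J24	0.616	0.698
Q319	0.606	0.695
J853	0.566	0.634
C8605	0.503	0.576
B73	0.491	0.569
200B	0.483	0.554
E28	0.421	0.503
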
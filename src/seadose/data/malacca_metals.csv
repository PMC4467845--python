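sample_code,location,element,concentration_mg_per_kg
Fi_Kl-1,Port Klang,Na,233.1
Fi_Kl-1,Port Klang,Mg,89.86
Fi_Kl-1,Port Klang,Al,4.488
Fi_Kl-1,Port Klang,K,483.2
Fi_Kl-1,Port Klang,Ca,6899
Fi_Kl-1,Port Klang,Cr,0.0432
Fi_Kl-1,Port Klang,Mn,1.985
Fi_Kl-1,Port Klang,Fe,4.843
Fi_Kl-1,Port Klang,Co,0.0027
Fi_Kl-1,Port Klang,Cu,0.0866
Fi_Kl-1,Port Klang,Zn,17.02
Fi_Kl-1,Port Klang,As,0.6061
Fi_Kl-1,Port Klang,Se,0.0471
Fi_Kl-1,Port Klang,Rb,0.2428
Fi_Kl-1,Port Klang,Sr,28.2
Fi_Kl-1,Port Klang,Mo,0.5767
Fi_Kl-1,Port Klang,Ba,0.2087
Fi_Kl-1,Port Klang,Bi,8.61
Fi_Kl-1,Port Klang,Hg,0.056
Fi_Kl-1,Port Klang,Pb,
Fi_Kl-2,Port Klang,Na,115.1
Fi_Kl-2,Port Klang,Mg,49.32
Fi_Kl-2,Port Klang,Al,2.816
Fi_Kl-2,Port Klang,K,290.2
Fi_Kl-2,Port Klang,Ca,2684
Fi_Kl-2,Port Klang,Cr,0.0028
Fi_Kl-2,Port Klang,Mn,0.1642
Fi_Kl-2,Port Klang,Fe,2.102
Fi_Kl-2,Port Klang,Co,
Fi_Kl-2,Port Klang,Cu,0.0314
Fi_Kl-2,Port Klang,Zn,1.888
Fi_Kl-2,Port Klang,As,0.5523
Fi_Kl-2,Port Klang,Se,0.0311
Fi_Kl-2,Port Klang,Rb,0.0647
Fi_Kl-2,Port Klang,Sr,11.41
Fi_Kl-2,Port Klang,Mo,0.7037
Fi_Kl-2,Port Klang,Ba,0.256
Fi_Kl-2,Port Klang,Bi,0.4822
Fi_Kl-2,Port Klang,Hg,0.014
Fi_Kl-2,Port Klang,Pb,
Fi_Kl-3,Port Klang,Na,231
Fi_Kl-3,Port Klang,Mg,102.1
Fi_Kl-3,Port Klang,Al,3.789
Fi_Kl-3,Port Klang,K,623.4
Fi_Kl-3,Port Klang,Ca,5592
Fi_Kl-3,Port Klang,Cr,0.0624
Fi_Kl-3,Port Klang,Mn,0.3926
Fi_Kl-3,Port Klang,Fe,3.692
Fi_Kl-3,Port Klang,Co,
Fi_Kl-3,Port Klang,Cu,0.0956
Fi_Kl-3,Port Klang,Zn,3.502
Fi_Kl-3,Port Klang,As,1.087
Fi_Kl-3,Port Klang,Se,0.0759
Fi_Kl-3,Port Klang,Rb,0.1603
Fi_Kl-3,Port Klang,Sr,23.46
Fi_Kl-3,Port Klang,Mo,1.407
Fi_Kl-3,Port Klang,Ba,0.5616
Fi_Kl-3,Port Klang,Bi,3.338
Fi_Kl-3,Port Klang,Hg,0.004
Fi_Kl-3,Port Klang,Pb,
Fi_Re-1,Pantai Remis,Na,220.9
Fi_Re-1,Pantai Remis,Mg,87.59
Fi_Re-1,Pantai Remis,Al,4.449
Fi_Re-1,Pantai Remis,K,464.7
Fi_Re-1,Pantai Remis,Ca,6980
Fi_Re-1,Pantai Remis,Cr,0.0453
Fi_Re-1,Pantai Remis,Mn,1.942
Fi_Re-1,Pantai Remis,Fe,4.796
Fi_Re-1,Pantai Remis,Co,0.0033
Fi_Re-1,Pantai Remis,Cu,0.0683
Fi_Re-1,Pantai Remis,Zn,15.17
Fi_Re-1,Pantai Remis,As,0.5288
Fi_Re-1,Pantai Remis,Se,0.034
Fi_Re-1,Pantai Remis,Rb,0.2314
Fi_Re-1,Pantai Remis,Sr,28.24
Fi_Re-1,Pantai Remis,Mo,0.4084
Fi_Re-1,Pantai Remis,Ba,0.1845
Fi_Re-1,Pantai Remis,Bi,9.181
Fi_Re-1,Pantai Remis,Hg,
Fi_Re-1,Pantai Remis,Pb,
Fi_Re-2,Pantai Remis,Na,219.5
Fi_Re-2,Pantai Remis,Mg,85.54
Fi_Re-2,Pantai Remis,Al,4.798
Fi_Re-2,Pantai Remis,K,459.7
Fi_Re-2,Pantai Remis,Ca,6487
Fi_Re-2,Pantai Remis,Cr,0.0514
Fi_Re-2,Pantai Remis,Mn,1.717
Fi_Re-2,Pantai Remis,Fe,4.883
Fi_Re-2,Pantai Remis,Co,0.0012
Fi_Re-2,Pantai Remis,Cu,0.0679
Fi_Re-2,Pantai Remis,Zn,14.96
Fi_Re-2,Pantai Remis,As,0.5305
Fi_Re-2,Pantai Remis,Se,0.0332
Fi_Re-2,Pantai Remis,Rb,0.2298
Fi_Re-2,Pantai Remis,Sr,26.88
Fi_Re-2,Pantai Remis,Mo,0.3128
Fi_Re-2,Pantai Remis,Ba,0.1616
Fi_Re-2,Pantai Remis,Bi,1.066
Fi_Re-2,Pantai Remis,Hg,
Fi_Re-2,Pantai Remis,Pb,
Fi_Re-3,Pantai Remis,Na,223.5
Fi_Re-3,Pantai Remis,Mg,88.53
Fi_Re-3,Pantai Remis,Al,5.301
Fi_Re-3,Pantai Remis,K,456.6
Fi_Re-3,Pantai Remis,Ca,6675
Fi_Re-3,Pantai Remis,Cr,0.058
Fi_Re-3,Pantai Remis,Mn,1.863
Fi_Re-3,Pantai Remis,Fe,4.893
Fi_Re-3,Pantai Remis,Co,0.0038
Fi_Re-3,Pantai Remis,Cu,0.0773
Fi_Re-3,Pantai Remis,Zn,15.91
Fi_Re-3,Pantai Remis,As,0.5393
Fi_Re-3,Pantai Remis,Se,0.0379
Fi_Re-3,Pantai Remis,Rb,0.2325
Fi_Re-3,Pantai Remis,Sr,27.93
Fi_Re-3,Pantai Remis,Mo,0.3034
Fi_Re-3,Pantai Remis,Ba,0.5075
Fi_Re-3,Pantai Remis,Bi,1.821
Fi_Re-3,Pantai Remis,Hg,
Fi_Re-3,Pantai Remis,Pb,
Fi_Bl-1,Bagan Lalang,Na,260.7
Fi_Bl-1,Bagan Lalang,Mg,115.4
Fi_Bl-1,Bagan Lalang,Al,3.508
Fi_Bl-1,Bagan Lalang,K,439.4
Fi_Bl-1,Bagan Lalang,Ca,6614
Fi_Bl-1,Bagan Lalang,Cr,0.0108
Fi_Bl-1,Bagan Lalang,Mn,0.4598
Fi_Bl-1,Bagan Lalang,Fe,4.111
Fi_Bl-1,Bagan Lalang,Co,0.0007
Fi_Bl-1,Bagan Lalang,Cu,0.2018
Fi_Bl-1,Bagan Lalang,Zn,5.577
Fi_Bl-1,Bagan Lalang,As,0.3237
Fi_Bl-1,Bagan Lalang,Se,0.0907
Fi_Bl-1,Bagan Lalang,Rb,0.098
Fi_Bl-1,Bagan Lalang,Sr,20.22
Fi_Bl-1,Bagan Lalang,Mo,2.719
Fi_Bl-1,Bagan Lalang,Ba,0.6917
Fi_Bl-1,Bagan Lalang,Bi,2.426
Fi_Bl-1,Bagan Lalang,Hg,
Fi_Bl-1,Bagan Lalang,Pb,0.02
Fi_Bl-2,Bagan Lalang,Na,250
Fi_Bl-2,Bagan Lalang,Mg,114.6
Fi_Bl-2,Bagan Lalang,Al,2.722
Fi_Bl-2,Bagan Lalang,K,436.4
Fi_Bl-2,Bagan Lalang,Ca,6241
Fi_Bl-2,Bagan Lalang,Cr,
Fi_Bl-2,Bagan Lalang,Mn,0.4146
Fi_Bl-2,Bagan Lalang,Fe,3.855
Fi_Bl-2,Bagan Lalang,Co,
Fi_Bl-2,Bagan Lalang,Cu,0.1936
Fi_Bl-2,Bagan Lalang,Zn,5.637
Fi_Bl-2,Bagan Lalang,As,0.3262
Fi_Bl-2,Bagan Lalang,Se,0.0969
Fi_Bl-2,Bagan Lalang,Rb,0.0975
Fi_Bl-2,Bagan Lalang,Sr,18.95
Fi_Bl-2,Bagan Lalang,Mo,2.541
Fi_Bl-2,Bagan Lalang,Ba,0.6276
Fi_Bl-2,Bagan Lalang,Bi,0.7697
Fi_Bl-2,Bagan Lalang,Hg,
Fi_Bl-2,Bagan Lalang,Pb,
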
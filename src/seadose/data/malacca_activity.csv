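sample_code,location,matrix,nuclide,activity_Bq_per_kg,uncertainty_Bq_per_kg
Fi_Bl-1,Bagan Lalang,fish,Ra-226,7.79,0.46
Fi_Bl-1,Bagan Lalang,fish,Th-232,6.06,0.36
Fi_Bl-1,Bagan Lalang,fish,K-40,387.6,18.8
Fi_Bl-2,Bagan Lalang,fish,Ra-226,8.16,1.08
Fi_Bl-2,Bagan Lalang,fish,Th-232,6.25,0.65
Fi_Bl-2,Bagan Lalang,fish,K-40,374.1,20.7
Fi_Bl-3,Bagan Lalang,fish,Ra-226,7.54,0.79
Fi_Bl-3,Bagan Lalang,fish,Th-232,6.31,0.58
Fi_Bl-3,Bagan Lalang,fish,K-40,316.0,17.0
Wa_Bl-1,Bagan Lalang,water,Ra-226,1.03,0.12
Wa_Bl-1,Bagan Lalang,water,Th-232,0.25,0.04
Wa_Bl-1,Bagan Lalang,water,K-40,15.2,1.4
Wa_Bl-2,Bagan Lalang,water,Ra-226,1.05,0.13
Wa_Bl-2,Bagan Lalang,water,Th-232,0.27,0.06
Wa_Bl-2,Bagan Lalang,water,K-40,17.3,1.5
Wa_Bl-3,Bagan Lalang,water,Ra-226,1.08,0.14
Wa_Bl-3,Bagan Lalang,water,Th-232,0.32,0.07
Wa_Bl-3,Bagan Lalang,water,K-40,16.7,1.5
Fi_Kl-1,Port Klang,fish,Ra-226,6.32,0.56
Fi_Kl-1,Port Klang,fish,Th-232,3.75,0.34
Fi_Kl-1,Port Klang,fish,K-40,371.5,19.2
Fi_Kl-2,Port Klang,fish,Ra-226,6.72,0.72
Fi_Kl-2,Port Klang,fish,Th-232,3.79,0.38
Fi_Kl-2,Port Klang,fish,K-40,442.4,22.6
Fi_Kl-3,Port Klang,fish,Ra-226,6.40,0.70
Fi_Kl-3,Port Klang,fish,Th-232,3.58,0.37
Fi_Kl-3,Port Klang,fish,K-40,382.6,18.9
Wa_Kl-1,Port Klang,water,Ra-226,1.02,0.16
Wa_Kl-1,Port Klang,water,Th-232,0.34,0.07
Wa_Kl-1,Port Klang,water,K-40,16.0,1.3
Wa_Kl-2,Port Klang,water,Ra-226,1.41,0.19
Wa_Kl-2,Port Klang,water,Th-232,0.37,0.08
Wa_Kl-2,Port Klang,water,K-40,14.5,1.2
Wa_Kl-3,Port Klang,water,Ra-226,1.25,0.18
Wa_Kl-3,Port Klang,water,Th-232,0.35,0.08
Wa_Kl-3,Port Klang,water,K-40,14.8,1.2
Fi_Re-1,Pantai Remis,fish,Ra-226,4.37,0.46
Fi_Re-1,Pantai Remis,fish,Th-232,1.62,0.21
Fi_Re-1,Pantai Remis,fish,K-40,268.7,13.8
Fi_Re-2,Pantai Remis,fish,Ra-226,3.77,0.47
Fi_Re-2,Pantai Remis,fish,Th-232,1.92,0.21
Fi_Re-2,Pantai Remis,fish,K-40,299.1,15.1
Fi_Re-3,Pantai Remis,fish,Ra-226,4.02,0.51
Fi_Re-3,Pantai Remis,fish,Th-232,2.25,0.30
Fi_Re-3,Pantai Remis,fish,K-40,296.6,15.5
Wa_Re-1,Pantai Remis,water,Ra-226,1.28,0.19
Wa_Re-1,Pantai Remis,water,Th-232,0.26,0.06
Wa_Re-1,Pantai Remis,water,K-40,20.1,1.7
Wa_Re-2,Pantai Remis,water,Ra-226,1.03,0.12
Wa_Re-2,Pantai Remis,water,Th-232,0.30,0.07
Wa_Re-2,Pantai Remis,water,K-40,20.1,1.6
Wa_Re-3,Pantai Remis,water,Ra-226,1.22,0.16
Wa_Re-3,Pantai Remis,water,Th-232,0.25,0.09
Wa_Re-3,Pantai Remis,water,K-40,19.5,1.7
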
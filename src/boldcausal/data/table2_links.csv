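seed,partner,task,lag,link,method
M-Tal,Cau,resting,0,undirected,PC
M-Tal,Cau,motor,0,undirected,PC
M-Tal,Put,resting,0,undirected,PC
M-Tal,Put,motor,0,undirected,PC
M-Tal,GPe,resting,0,undirected,PC
M-Tal,GPe,motor,0,undirected,PC
M-Tal,STN,resting,0,undirected,PC
M-Tal,STN,motor,0,undirected,PC
M-Tal,S1,resting,0,undirected,PC
M-Tal,M1,motor,0,undirected,PC
M-Tal,Put,resting,1,causative,PC
M-Tal,Cau,resting,2,causative,PC
M-Tal,Cau,resting,2,response,PC
M-Tal,M1,resting,0,undirected,GPDC
M-Tal,M1,motor,0,undirected,GPDC
M-Tal,Cau,resting,0,undirected,GPDC
M-Tal,Cau,motor,0,undirected,GPDC
M-Tal,Put,resting,0,undirected,GPDC
M-Tal,Put,motor,0,undirected,GPDC
M-Tal,GPe,resting,0,undirected,GPDC
M-Tal,GPe,motor,0,undirected,GPDC
M-Tal,S1,resting,0,undirected,GPDC
M-Tal,STN,motor,0,undirected,GPDC
M-Tal,Put,motor,2,causative,GPDC
M-Tal,Cau,motor,2,causative,GPDC
M-Tal,GPe,motor,2,causative,GPDC
M-Tal,STN,resting,1,response,GPDC
M-Tal,Cau,resting,2,response,GPDC
M-Tal,Cau,motor,2,response,GPDC
M-Tal,SN,resting,2,response,GPDC
M-Tal,Cau,resting,0,undirected,CMIknn
M-Tal,Cau,motor,0,undirected,CMIknn
M-Tal,Put,resting,0,undirected,CMIknn
M-Tal,Put,motor,0,undirected,CMIknn
M-Tal,GPe,resting,0,undirected,CMIknn
M-Tal,GPe,motor,0,undirected,CMIknn
M-Tal,STN,resting,0,undirected,CMIknn
M-Tal,STN,motor,0,undirected,CMIknn
M-Tal,SN,resting,0,undirected,CMIknn
M-Tal,Cau,resting,2,causative,CMIknn
M-Tal,Cau,motor,2,causative,CMIknn
M-Tal,M1,resting,0,causative,CMIknn
M-Tal,M1,motor,0,causative,CMIknn
M-Tal,S1,resting,0,causative,CMIknn
IL-Tal,Cau,resting,0,undirected,PC
IL-Tal,Cau,motor,0,undirected,PC
IL-Tal,Put,resting,0,undirected,PC
IL-Tal,Put,motor,0,undirected,PC
IL-Tal,GPe,resting,0,undirected,PC
IL-Tal,GPe,motor,0,undirected,PC
IL-Tal,STN,resting,0,undirected,PC
IL-Tal,STN,motor,0,undirected,PC
IL-Tal,GPi,resting,0,undirected,PC
IL-Tal,GPi,motor,0,undirected,PC
IL-Tal,Cau,motor,2,causative,PC
IL-Tal,Cau,resting,0,undirected,GPDC
IL-Tal,Cau,motor,0,undirected,GPDC
IL-Tal,Put,resting,0,undirected,GPDC
IL-Tal,Put,motor,0,undirected,GPDC
IL-Tal,GPe,resting,0,undirected,GPDC
IL-Tal,GPe,motor,0,undirected,GPDC
IL-Tal,STN,resting,0,undirected,GPDC
IL-Tal,STN,motor,0,undirected,GPDC
IL-Tal,GPi,resting,0,undirected,GPDC
IL-Tal,GPi,motor,0,undirected,GPDC
IL-Tal,GPe,resting,2,causative,GPDC
IL-Tal,GPe,motor,2,causative,GPDC
IL-Tal,Cau,motor,2,causative,GPDC
IL-Tal,S1,motor,2,causative,GPDC
IL-Tal,M1,motor,2,causative,GPDC
IL-Tal,Cau,resting,0,undirected,CMIknn
IL-Tal,Cau,motor,0,undirected,CMIknn
IL-Tal,Put,resting,0,undirected,CMIknn
IL-Tal,Put,motor,0,undirected,CMIknn
IL-Tal,GPe,resting,0,undirected,CMIknn
IL-Tal,GPe,motor,0,undirected,CMIknn
IL-Tal,STN,resting,0,undirected,CMIknn
IL-Tal,STN,motor,0,undirected,CMIknn
IL-Tal,GPi,resting,0,undirected,CMIknn
IL-Tal,GPi,motor,0,undirected,CMIknn
IL-Tal,SN,resting,0,causative,CMIknn
MD-Tal,Put,resting,0,undirected,PC
MD-Tal,Put,motor,0,undirected,PC
MD-Tal,Cau,resting,1,causative,PC
MD-Tal,GPe,motor,1,causative,PC
MD-Tal,Cau,resting,2,response,PC
MD-Tal,Cau,motor,2,response,PC
MD-Tal,M1,motor,2,response,PC
MD-Tal,S1,resting,2,response,PC
MD-Tal,Cau,resting,0,undirected,GPDC
MD-Tal,Cau,motor,0,undirected,GPDC
MD-Tal,Put,resting,0,undirected,GPDC
MD-Tal,Put,motor,0,undirected,GPDC
MD-Tal,GPe,resting,0,undirected,GPDC
MD-Tal,GPe,motor,0,undirected,GPDC
MD-Tal,STN,resting,0,undirected,GPDC
MD-Tal,STN,motor,0,undirected,GPDC
MD-Tal,M1,motor,0,undirected,GPDC
MD-Tal,GPi,motor,0,undirected,GPDC
MD-Tal,SN,motor,0,undirected,GPDC
MD-Tal,Cau,resting,1,causative,GPDC
MD-Tal,Put,resting,1,causative,GPDC
MD-Tal,Put,motor,1,causative,GPDC
MD-Tal,GPe,resting,1,causative,GPDC
MD-Tal,GPe,motor,1,causative,GPDC
MD-Tal,SN,resting,1,response,GPDC
MD-Tal,SN,motor,1,response,GPDC
MD-Tal,STN,resting,1,response,GPDC
MD-Tal,M1,resting,2,response,GPDC
MD-Tal,M1,motor,2,response,GPDC
MD-Tal,Cau,resting,2,response,GPDC
MD-Tal,Cau,motor,2,response,GPDC
MD-Tal,Put,resting,0,undirected,CMIknn
MD-Tal,Put,motor,0,undirected,CMIknn
MD-Tal,S1,resting,0,causative,CMIknn
MD-Tal,Cau,resting,1,causative,CMIknn
MD-Tal,Cau,motor,2,causative,CMIknn
MD-Tal,GPe,resting,0,response,CMIknn
MD-Tal,SN,motor,0,response,CMIknn
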